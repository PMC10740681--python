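"""Synthetic survey generator: gradient, traits, environmental filtering.

Emulates the data structure of a monthly multi-site plankton survey: a
latent trophic score per sample spanning a mesotrophic-to-eutrophic range,
water chemistry back-solved from that score (so the composite index
round-trips), a categorical trait table, and a community assembled from a
Gaussian niche model on the trophic axis,

    abundance(i, s) = baseline_i * exp(-kappa * (T_s - opt_i)^2 / (2 w_i^2))
                      * lognormal observation noise,

where species carrying "tolerant" trait modalities receive optima in the
eutrophic part of the gradient.  With ``kappa = 0`` abundances are
independent of the gradient (neutral assembly); large ``kappa``
concentrates abundance of eutrophic samples in the tolerant species,
producing the environmental filtering and functional homogenization the
downstream analyses are designed to detect.

Seed policy: a single ``master_seed``; each stage draws from
``master_seed + <fixed offset>`` so stages can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CommunityMatrix
from .errors import ConfigurationError, ValidationError
from .functional_traits import DEFAULT_VOCABULARY
from .trophic_state import (
    COEFFICIENT_SETS,
    PARAMETERS,
    TLICoefficients,
    composite_tli,
)

# Fixed child-seed offsets (see module docstring).
TRAIT_SEED_OFFSET = 1
ENV_SEED_OFFSET = 2
COMMUNITY_SEED_OFFSET = 3
MISSING_SEED_OFFSET = 4
OBSERVATION_SEED_OFFSET = 5

#: Trait modalities whose carriers get optima in the eutrophic range.
DEFAULT_TOLERANT_MODALITIES: dict[str, str] = {
    "trophi": "malleate",
    "feeding": "filter-feeding",
    "swimming": "planktonic",
}

#: Feeding habit implied by each jaw-apparatus type (trait syndrome):
#: malleate and ramate jaws filter, the asymmetrical virgate type preys,
#: the virgate type sucks, and the remaining types are carnivorous.
TROPHI_FEEDING_LINKAGE: dict[str, str] = {
    "malleate": "filter-feeding",
    "ramate": "filter-feeding",
    "asymmetrical virgate": "predacious",
    "virgate": "sucking",
    "incudate": "carnivorous",
    "malleoramate": "carnivorous",
    "forcipate": "carnivorous",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic survey.

    ``filtering_strength`` (kappa) scales the Gaussian niche penalty
    (0 = neutral); ``dominance_concentration`` (theta) widens the baseline
    lognormal rank-abundance curve; ``noise_sigma`` is the multiplicative
    noise on back-solved chemistry; ``observation_sigma`` the per-cell
    lognormal noise on abundances.
    """

    n_sites: int = 10
    n_months: int = 12
    n_species: int = 46
    trait_vocabulary: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARY)
    )
    gradient_range: tuple[float, float] = (45.0, 65.0)
    filtering_strength: float = 3.0
    dominance_concentration: float = 1.0
    missing_sample_rate: float = 2.0 / 120.0
    master_seed: int = 0
    noise_sigma: float = 0.05
    observation_sigma: float = 1.3
    detection_limit: float = 0.05
    tolerance_range: tuple[float, float] = (0.20, 0.35)
    niche_shape: str = "onesided"
    baseline_scale: float = 50.0
    tolerant_modalities: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TOLERANT_MODALITIES)
    )
    coefficient_set: str = "canonical"

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ConfigurationError("n_species must be >= 4")
        if self.n_sites < 1 or self.n_months < 1:
            raise ConfigurationError("n_sites and n_months must be >= 1")
        lo, hi = self.gradient_range
        if not (lo <= hi):
            raise ConfigurationError("gradient_range low must be <= high")
        if lo < hi and not (0.0 < lo < hi < 100.0):
            raise ConfigurationError("gradient_range must lie inside (0, 100)")
        if lo == hi and not (0.0 < lo < 100.0):
            raise ConfigurationError("gradient_range must lie inside (0, 100)")
        for cat, mods in self.trait_vocabulary.items():
            if len(mods) < 2:
                raise ConfigurationError(
                    f"trait category {cat!r} needs >= 2 modalities"
                )
        if self.filtering_strength < 0:
            raise ConfigurationError("filtering_strength must be >= 0")
        if self.dominance_concentration < 0:
            raise ConfigurationError("dominance_concentration must be >= 0")
        if not (0.0 <= self.missing_sample_rate < 1.0):
            raise ConfigurationError("missing_sample_rate must be in [0, 1)")
        if self.coefficient_set not in COEFFICIENT_SETS:
            raise ConfigurationError(
                f"unknown coefficient_set {self.coefficient_set!r}"
            )
        if self.niche_shape not in ("onesided", "gaussian"):
            raise ConfigurationError(f"unknown niche_shape {self.niche_shape!r}")

    @property
    def coefficients(self) -> TLICoefficients:
        return COEFFICIENT_SETS[self.coefficient_set]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["trait_vocabulary"] = {k: list(v) for k, v in d["trait_vocabulary"].items()}
        d["tolerant_modalities"] = dict(d["tolerant_modalities"])
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    """Everything a downstream analysis needs, plus the generating truth."""

    community: CommunityMatrix
    traits: pd.DataFrame
    environment: pd.DataFrame
    truth_species: pd.DataFrame  # taxon, optimum, tolerance, tolerant_score
    truth_samples: pd.DataFrame  # sample_id, latent_tli
    config: SimulationConfig


def _taxon_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"sp{i + 1:0{width}d}" for i in range(n)]


def generate_trait_table(
    n_species: int,
    vocabulary: Mapping[str, Sequence[str]] = DEFAULT_VOCABULARY,
    seed: int = 0,
    link_feeding: bool = True,
) -> pd.DataFrame:
    """Assign each taxon one modality per category, deterministically.

    Whenever ``n_species`` is at least a category's modality count, every
    modality of that category is used at least once.  When the vocabulary
    contains the standard jaw-apparatus types and ``link_feeding`` is true,
    the feeding habit is derived from the trophi type via
    :data:`TROPHI_FEEDING_LINKAGE` (a realistic trait syndrome that gives
    the community functional redundancy); coverage of the feeding
    modalities then follows from coverage of the trophi modalities.
    """
    if n_species < 1:
        raise ConfigurationError("n_species must be >= 1")
    for cat, mods in vocabulary.items():
        if len(mods) == 0:
            raise ConfigurationError(f"trait category {cat!r} has no modalities")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=pd.Index(_taxon_names(n_species), name="taxon"))
    linkage_ok = (
        link_feeding
        and "trophi" in vocabulary
        and "feeding" in vocabulary
        and set(vocabulary["trophi"]) <= set(TROPHI_FEEDING_LINKAGE)
        and set(TROPHI_FEEDING_LINKAGE[t] for t in vocabulary["trophi"])
        == set(vocabulary["feeding"])
    )
    for cat, mods in vocabulary.items():
        if cat == "feeding" and linkage_ok:
            continue
        mods = list(mods)
        if n_species >= len(mods):
            assigned = mods + list(rng.choice(mods, size=n_species - len(mods)))
        else:
            assigned = list(rng.choice(mods, size=n_species, replace=False))
        rng.shuffle(assigned)
        out[cat] = assigned
    if linkage_ok:
        out["feeding"] = out["trophi"].map(TROPHI_FEEDING_LINKAGE)
    return out[list(vocabulary)]


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    sites = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    rows = [
        {"sample_id": f"{site}_M{month:02d}", "site": site, "month": month}
        for site in sites
        for month in range(1, config.n_months + 1)
    ]
    return pd.DataFrame(rows)


def generate_env_gradient(config: SimulationConfig) -> pd.DataFrame:
    """Environment table whose chemistry encodes a latent trophic gradient.

    Latent targets combine a per-site level (spanning the gradient range), a
    seasonal cosine and noise, clipped to the range; chemistry is back-solved
    per parameter as ``x_j = exp((T/10 - a_j)/b_j + sigma * eps)`` so that
    recomputing the composite index recovers the targets up to noise.  The
    returned frame carries the extra column ``latent_tli`` (dropped by the
    canonical CSV writer) plus plausible temp/dep/do/ph columns.
    """
    rng = np.random.default_rng(config.master_seed + ENV_SEED_OFFSET)
    lo, hi = config.gradient_range
    span = hi - lo
    frame = _sample_frame(config)

    site_levels = (
        np.linspace(lo + 0.12 * span, hi - 0.12 * span, config.n_sites)
        if config.n_sites > 1
        else np.array([(lo + hi) / 2.0])
    )
    rng.shuffle(site_levels)
    site_of = {f"S{i + 1:02d}": site_levels[i] for i in range(config.n_sites)}
    month = frame["month"].to_numpy()
    seasonal = 0.10 * span * np.cos(2.0 * np.pi * (month - 4) / 12.0)
    noise = rng.normal(0.0, 0.05 * span, size=len(frame))
    latent = np.clip(
        frame["site"].map(site_of).to_numpy() + seasonal + noise, lo, hi
    )

    coeffs = config.coefficients
    env = frame.copy()
    for p in PARAMETERS:
        a, b = coeffs.params[p]
        eps = rng.normal(0.0, config.noise_sigma, size=len(frame))
        env[p] = np.exp((latent / 10.0 - a) / b + eps)
    env["temp"] = np.round(
        16.0 + 10.0 * np.cos(2.0 * np.pi * (month - 7) / 12.0)
        + rng.normal(0.0, 1.5, len(frame)),
        2,
    )
    env["dep"] = np.round(rng.uniform(1.0, 5.0, len(frame)), 2)
    env["do"] = np.round(
        np.clip(13.0 - 0.08 * latent + rng.normal(0.0, 0.8, len(frame)), 0.5, None), 2
    )
    env["ph"] = np.round(rng.normal(7.9, 0.25, len(frame)), 2)
    env["latent_tli"] = latent

    n_drop = int(round(config.missing_sample_rate * len(env)))
    if n_drop > 0:
        drop_rng = np.random.default_rng(config.master_seed + MISSING_SEED_OFFSET)
        dropped = drop_rng.choice(len(env), size=n_drop, replace=False)
        env = env.drop(index=env.index[dropped]).reset_index(drop=True)
    return env


def generate_communities(
    traits: pd.DataFrame,
    environment: pd.DataFrame,
    config: SimulationConfig,
) -> SyntheticDataset:
    """Assemble abundances with the Gaussian niche model on the latent axis."""
    if len(traits) == 0 or len(environment) == 0:
        raise ValidationError("traits and environment must be nonempty")
    traits = traits.set_index("taxon") if "taxon" in traits.columns else traits
    if traits.index.has_duplicates:
        raise ValidationError("duplicate taxa in trait table")
    if "sample_id" not in environment.columns:
        raise ValidationError("environment table needs a sample_id column")
    if environment["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in environment table")

    rng = np.random.default_rng(config.master_seed + COMMUNITY_SEED_OFFSET)
    lo, hi = config.gradient_range
    span = hi - lo

    if "latent_tli" in environment.columns:
        latent = environment["latent_tli"].to_numpy(dtype=float)
    else:
        latent = composite_tli(environment, config.coefficients).tlic.to_numpy()

    # tolerance score: fraction of tolerant modalities each species carries
    score = np.zeros(len(traits))
    tol = config.tolerant_modalities
    for cat, modality in tol.items():
        if cat in traits.columns:
            score += (traits[cat] == modality).to_numpy(dtype=float)
    score /= max(len(tol), 1)

    if span > 0:
        # steep score -> optimum map: fully tolerant species sit at the
        # eutrophic edge; intolerant species scatter over the lower half
        jitter = 0.10 * (1.0 - 0.6 * score) * span
        optimum = (
            lo
            + (0.05 + 0.95 * score) * span
            + rng.normal(0.0, 1.0, len(traits)) * jitter
        )
        t_lo, t_hi = config.tolerance_range
        tolerance = rng.uniform(t_lo, t_hi, len(traits)) * span
    else:
        optimum = np.full(len(traits), lo) + rng.normal(0.0, 1.0, len(traits))
        tolerance = np.full(len(traits), 1.0)

    sigma_base = 0.5 + 0.5 * config.dominance_concentration
    baseline = config.baseline_scale * np.exp(
        rng.normal(0.0, sigma_base, len(traits))
    )

    kappa = config.filtering_strength
    if span > 0 and kappa > 0:
        delta = latent[:, None] - optimum[None, :]
        if config.niche_shape == "onesided":
            # stress response: only trophic state above a species' optimum
            # penalizes it, so the low end of the gradient is benign
            delta = np.maximum(delta, 0.0)
        elif config.niche_shape != "gaussian":
            raise ConfigurationError(
                f"unknown niche_shape {config.niche_shape!r}"
            )
        niche = np.exp(-kappa * delta**2 / (2.0 * tolerance[None, :] ** 2))
    else:
        niche = np.ones((len(latent), len(traits)))

    obs_rng = np.random.default_rng(config.master_seed + OBSERVATION_SEED_OFFSET)
    noise = np.exp(
        obs_rng.normal(0.0, config.observation_sigma, size=(len(latent), len(traits)))
    )
    x = baseline[None, :] * niche * noise

    # detection limit -> real absences; keep each sample's largest cell
    below = x < config.detection_limit
    keep = np.zeros_like(below)
    keep[np.arange(len(x)), x.argmax(axis=1)] = True
    x = np.where(below & ~keep, 0.0, x)

    abundance = pd.DataFrame(
        x, index=pd.Index(environment["sample_id"], name="sample_id"),
        columns=traits.index,
    )
    meta = environment.set_index("sample_id")[["site", "month"]].copy()
    community = CommunityMatrix(abundance=abundance, meta=meta)

    truth_species = pd.DataFrame(
        {
            "taxon": traits.index,
            "optimum": optimum,
            "tolerance": tolerance,
            "tolerant_score": score,
        }
    )
    truth_samples = pd.DataFrame(
        {"sample_id": environment["sample_id"].to_numpy(), "latent_tli": latent}
    )
    return SyntheticDataset(
        community=community,
        traits=traits,
        environment=environment,
        truth_species=truth_species,
        truth_samples=truth_samples,
        config=config,
    )


def generate_dataset(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """One-call generation of traits, environment and community."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    traits = generate_trait_table(
        config.n_species, config.trait_vocabulary,
        seed=config.master_seed + TRAIT_SEED_OFFSET,
    )
    environment = generate_env_gradient(config)
    return generate_communities(traits, environment, config)
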