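import numpy as np
import pandas as pd
import pytest

import rotifd
from rotifd.beta_partition import braycurtis_matrix
from rotifd.datatypes import CommunityMatrix
from rotifd.functional_diversity import TraitSpace
from rotifd.functional_traits import TRAIT_CATEGORIES, composition_by_modality


@pytest.fixture
def small_traits() -> pd.DataFrame:
    """Four taxa covering distinct modality combinations."""
    return pd.DataFrame(
        {
            "taxon": ["t1", "t2", "t3", "t4"],
            "trophi": ["malleate", "virgate", "incudate", "malleate"],
            "size": ["<150 um", "150-300 um", ">300 um", "<150 um"],
            "feeding": ["filter-feeding", "sucking", "carnivorous", "filter-feeding"],
            "swimming": ["planktonic", "benthic", "planktonic", "planktonic"],
        }
    ).set_index("taxon")


@pytest.fixture
def small_community(small_traits) -> CommunityMatrix:
    abundance = pd.DataFrame(
        {
            "t1": [30.0, 5.0, 0.0],
            "t2": [10.0, 5.0, 12.0],
            "t3": [0.0, 2.0, 8.0],
            "t4": [4.0, 0.0, 1.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    meta = pd.DataFrame(
        {"site": ["A", "A", "B"], "month": [1, 2, 1]}, index=abundance.index
    )
    return CommunityMatrix(abundance=abundance, meta=meta)


def make_space(coords: np.ndarray, taxa=None) -> TraitSpace:
    """Build a TraitSpace directly from coordinates (for index oracles)."""
    coords = np.asarray(coords, dtype=float)
    if taxa is None:
        taxa = [f"x{i}" for i in range(len(coords))]
    frame = pd.DataFrame(
        coords, index=pd.Index(taxa, name="taxon"),
        columns=[f"axis{i + 1}" for i in range(coords.shape[1])],
    )
    eig = np.ones(coords.shape[1])
    return TraitSpace(coordinates=frame, eigenvalues=eig, correction="none", quality=1.0)


def random_abundance_pair(rng: np.random.Generator, n_taxa: int = 12) -> pd.DataFrame:
    """Two random communities over a shared taxon pool, with absences."""
    x = rng.gamma(0.5, 10.0, size=(2, n_taxa))
    x[rng.random((2, n_taxa)) < 0.35] = 0.0
    if x[0].sum() == 0:
        x[0, 0] = 1.0
    if x[1].sum() == 0:
        x[1, 1] = 1.0
    return pd.DataFrame(x, index=["u", "v"], columns=[f"t{i}" for i in range(n_taxa)])


def _tri_mean(frame: pd.DataFrame) -> float:
    m = frame.to_numpy()
    return float(m[np.triu_indices(len(m), k=1)].mean())


def run_recovery_seed(seed: int, kappa: float) -> dict:
    """One full pipeline run; returns the summary statistics used by the
    filtering-recovery and homogenization checks."""
    ds = rotifd.generate_dataset(master_seed=seed, filtering_strength=kappa)
    tli = rotifd.composite_tli(ds.environment)
    space = rotifd.build_trait_space(ds.traits)
    fd = rotifd.functional_diversity_table(ds.community, space)
    merged = tli.table.join(fd)
    sub = merged[["tlic", "feve"]].dropna()
    slope = rotifd.simple_regression(sub["tlic"], sub["feve"]).slope
    rels = pd.concat(
        [
            composition_by_modality(ds.community, ds.traits, cat).relative
            for cat in TRAIT_CATEGORIES
        ],
        axis=1,
    )
    t = tli.tlic
    hi = rels.loc[t[t >= t.quantile(0.75)].index]
    lo = rels.loc[t[t <= t.quantile(0.25)].index]
    return {
        "slope": slope,
        "bc_high": _tri_mean(braycurtis_matrix(hi)),
        "bc_low": _tri_mean(braycurtis_matrix(lo)),
    }


@pytest.fixture(scope="session")
def recovery_runs_k5() -> list[dict]:
    """Seeds 1-50 at filtering strength 5 (shared across tests)."""
    return [run_recovery_seed(seed, 5.0) for seed in range(1, 51)]


@pytest.fixture(scope="session")
def recovery_runs_k0() -> list[dict]:
    """Seeds 1-50 neutral (shared across tests)."""
    return [run_recovery_seed(seed, 0.0) for seed in range(1, 51)]
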