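"""Composite trophic level index (TLI).

Each water-chemistry parameter is scored on a 0-100 index scale as
``TLI_j = 10 * (a_j + b_j * ln(x_j))`` and the composite ``TLIc`` is the
weighted sum ``sum_j W_j * TLI_j`` with correlation-derived weights
``W_j = r_j**2 / sum(r**2)``.  Two named coefficient sets are shipped:

``canonical``
    The standard Chinese lake-survey coefficients for Chl-a, TP, TN,
    Secchi depth and CODMn.
``as_printed``
    A variant in which the SD equation duplicates the TP coefficients and
    COD carries the canonical SD constants; retained so published numbers
    computed with that (likely corrupted) set can be reproduced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateError, DomainError

logger = logging.getLogger(__name__)

#: Fixed parameter order for weights and reference correlations.
PARAMETERS = ("chla", "tp", "tn", "sd", "cod")

#: Default reference correlations of each parameter with Chl-a.
DEFAULT_REFERENCE_R = (1.0, 0.84, 0.82, 0.83, 0.83)

#: Trophic-state class boundaries on the TLIc scale:
#: below the first -> oligotrophic, above the second -> eutrophic,
#: boundaries inclusive to mesotrophic.
DEFAULT_CLASS_BOUNDS = (30.0, 50.0)

CLASS_LABELS = ("oligotrophic", "mesotrophic", "eutrophic")


@dataclass(frozen=True)
class TLICoefficients:
    """Per-parameter intercept/slope pairs for ``10*(a + b*ln x)``.

    Attributes
    ----------
    label
        Name of the coefficient set ("canonical", "as_printed" or custom).
    params
        Mapping parameter name -> (a, b).
    reference_r
        Reference correlations in :data:`PARAMETERS` order, used to derive
        the composite weights.
    """

    label: str
    params: Mapping[str, tuple[float, float]]
    reference_r: tuple[float, ...] = DEFAULT_REFERENCE_R

    def __post_init__(self) -> None:
        missing = [p for p in PARAMETERS if p not in self.params]
        if missing:
            raise ConfigurationError(f"coefficient set lacks parameters: {missing}")
        if len(self.reference_r) != len(PARAMETERS):
            raise ConfigurationError(
                "reference_r must have one entry per parameter "
                f"({len(PARAMETERS)}), got {len(self.reference_r)}"
            )

    def weights(self) -> pd.Series:
        """Correlation-derived weights, one per parameter, summing to 1."""
        w = weights_from_correlations(self.reference_r)
        return pd.Series(w, index=list(PARAMETERS), name="weight")


CANONICAL = TLICoefficients(
    label="canonical",
    params={
        "chla": (2.5, 1.086),
        "tp": (9.436, 1.624),
        "tn": (5.453, 1.694),
        "sd": (5.118, -1.94),
        "cod": (0.109, 2.661),
    },
)

AS_PRINTED = TLICoefficients(
    label="as_printed",
    params={
        "chla": (2.5, 1.086),
        "tp": (9.436, 1.624),
        "tn": (5.453, 1.694),
        "sd": (9.436, 1.624),
        "cod": (5.118, 1.94),
    },
)

COEFFICIENT_SETS: dict[str, TLICoefficients] = {
    "canonical": CANONICAL,
    "as_printed": AS_PRINTED,
}


@dataclass
class TLIResult:
    """Per-sample subscores, composite index and trophic class.

    Attributes
    ----------
    table
        DataFrame indexed by sample_id with columns ``tli_<param>`` for every
        parameter, ``tlic`` and ``trophic_class``.
    weights
        Series of W_j in parameter order (sums to 1).
    coefficient_set
        Label of the coefficient set used.
    m
        Number of parameters entering the composite.
    skipped
        sample_ids dropped because of missing parameters (skip policy only).
    """

    table: pd.DataFrame
    weights: pd.Series
    coefficient_set: str
    m: int
    skipped: list = field(default_factory=list)

    @property
    def tlic(self) -> pd.Series:
        return self.table["tlic"]


def tli_parameter(
    parameter: str,
    value,
    coefficients: TLICoefficients = CANONICAL,
    *,
    sample: str | None = None,
):
    """Score one parameter: ``10 * (a + b * ln(value))``.

    ``value`` may be a scalar or an array; natural logarithm throughout.

    Raises
    ------
    ConfigurationError
        If ``parameter`` is not in the coefficient set.
    DomainError
        If any value is nonpositive (names the sample when given).
    """
    if parameter not in coefficients.params:
        raise ConfigurationError(
            f"unknown parameter {parameter!r}; expected one of {sorted(coefficients.params)}"
        )
    a, b = coefficients.params[parameter]
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        where = f" (sample {sample})" if sample is not None else ""
        raise DomainError(
            f"parameter {parameter!r} requires strictly positive values{where}"
        )
    out = 10.0 * (a + b * np.log(arr))
    return float(out) if np.isscalar(value) else out


def weights_from_correlations(r: Sequence[float]) -> np.ndarray:
    """Squared-correlation weights ``W_j = r_j^2 / sum(r^2)``.

    Sign-invariant in each ``r_j``; the result sums to exactly 1.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise DegenerateError("empty correlation vector")
    sq = r**2
    total = sq.sum()
    if total == 0:
        raise DegenerateError("all reference correlations are zero")
    return sq / total


def classify_trophic_state(tlic, bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS):
    """Map a composite index value to a trophic-state class.

    ``tlic < bounds[0]`` -> oligotrophic; ``tlic > bounds[1]`` -> eutrophic;
    the closed interval between (boundaries included) -> mesotrophic.
    """
    arr = np.asarray(tlic, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("TLIc must be finite for classification")
    lo, hi = bounds
    labels = np.where(arr < lo, CLASS_LABELS[0], np.where(arr > hi, CLASS_LABELS[2], CLASS_LABELS[1]))
    if np.isscalar(tlic) or arr.ndim == 0:
        return str(labels)
    return labels


def composite_tli(
    env: pd.DataFrame,
    coefficients: TLICoefficients = CANONICAL,
    *,
    missing_policy: str = "skip",
    bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS,
) -> TLIResult:
    """Score every sample of an environment table.

    Parameters
    ----------
    env
        DataFrame with a ``sample_id`` column or index and one column per
        parameter in :data:`PARAMETERS` (extra columns are ignored).
    missing_policy
        ``"skip"`` drops samples with missing parameter values (logged);
        ``"renormalize"`` scores them with weights renormalized over the
        available parameters.
    """
    if missing_policy not in ("skip", "renormalize"):
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    frame = env.set_index("sample_id") if "sample_id" in env.columns else env.copy()
    absent = [p for p in PARAMETERS if p not in frame.columns]
    if absent:
        raise ConfigurationError(f"environment table lacks columns: {absent}")

    weights = coefficients.weights()
    sub = pd.DataFrame(index=frame.index)
    for p in PARAMETERS:
        vals = frame[p].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if np.any(vals[ok] <= 0):
            bad = frame.index[ok & (vals <= 0)][0]
            raise DomainError(
                f"parameter {p!r} must be strictly positive (sample {bad})"
            )
        col = np.full(len(frame), np.nan)
        col[ok] = 10.0 * (
            coefficients.params[p][0] + coefficients.params[p][1] * np.log(vals[ok])
        )
        sub[f"tli_{p}"] = col

    have = sub.notna().to_numpy()
    w = weights.to_numpy()
    skipped: list = []
    if missing_policy == "skip":
        complete = have.all(axis=1)
        skipped = list(sub.index[~complete])
        if skipped:
            logger.warning(
                "skipping %d sample(s) with missing parameters: %s",
                len(skipped), skipped[:10],
            )
        sub = sub.loc[complete]
        tlic = sub.to_numpy() @ w
    else:
        scores = sub.to_numpy(copy=True)
        scores[~have] = 0.0
        denom = have @ w
        if np.any(denom == 0):
            empty = sub.index[denom == 0]
            logger.warning("samples with no scorable parameter dropped: %s", list(empty))
            keep = denom > 0
            sub, scores, have, denom = sub.loc[keep], scores[keep], have[keep], denom[keep]
        tlic = (scores @ w) / denom

    if len(sub) == 0:
        raise DegenerateError("no scorable samples in environment table")

    table = sub.copy()
    table["tlic"] = tlic
    table["trophic_class"] = classify_trophic_state(tlic, bounds)
    return TLIResult(
        table=table,
        weights=weights,
        coefficient_set=coefficients.label,
        m=len(PARAMETERS),
        skipped=skipped,
    )


def invert_tli_parameter(
    parameter: str, tli_value: float, coefficients: TLICoefficients = CANONICAL
) -> float:
    """Concentration whose subscore equals ``tli_value`` (used by the simulator)."""
    a, b = coefficients.params[parameter]
    return math.exp((tli_value / 10.0 - a) / b)
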