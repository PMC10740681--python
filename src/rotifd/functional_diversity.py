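"""Trait space construction and distance-based functional diversity indices.

The pipeline is: categorical trait table -> pairwise trait distances
(Gower or Bray-Curtis on one-hot indicators) -> principal coordinate
analysis (with an additive-constant correction when the distances are
non-Euclidean) -> per-sample indices on the retained axes:

FRic
    Convex-hull volume of the species present in a sample.
FEve
    Evenness of abundance along the minimum spanning tree linking the
    species present; in [0, 1].
FDiv
    Abundance-weighted divergence of species from the centre of the
    occupied space; in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .datatypes import CommunityMatrix, as_abundance
from .errors import ConfigurationError, DegenerateError, DomainError
from .functional_traits import TRAIT_CATEGORIES

_EIG_TOL = 1e-9


class IndexValue(NamedTuple):
    """An index value with an optional undefined-reason flag."""

    value: float
    flag: str | None = None

    @property
    def defined(self) -> bool:
        return self.flag is None


@dataclass
class TraitSpace:
    """Species coordinates from a (corrected) PCoA of trait distances.

    Attributes
    ----------
    coordinates
        taxon x axis DataFrame (columns ``axis1..axisk``).
    eigenvalues
        All eigenvalues of the final double-centred matrix, sorted
        descending.
    correction
        ``"none"`` or ``"additive"`` (Cailliez constant actually applied).
    quality
        Fraction of the positive eigenvalue mass carried by the retained
        axes.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    correction: str
    quality: float

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    @property
    def taxa(self) -> pd.Index:
        return self.coordinates.index


def trait_distance(traits: pd.DataFrame, method: str = "gower") -> pd.DataFrame:
    """Pairwise distances between taxa from categorical traits.

    ``gower``: mean per-category mismatch (0/1 per trait).
    ``braycurtis_indicator``: Bray-Curtis on the per-category one-hot
    indicator block, each category weighted equally.  For single-modality
    categorical traits both reduce to mismatch/|categories| and therefore
    give the same rank order.
    """
    traits = traits.set_index("taxon") if "taxon" in traits.columns else traits
    cats = [c for c in TRAIT_CATEGORIES if c in traits.columns]
    if not cats:
        cats = list(traits.columns)
    if len(traits) < 2:
        raise DomainError("need at least two taxa to compute trait distances")

    if method == "gower":
        codes = np.column_stack(
            [pd.factorize(traits[c].to_numpy())[0] for c in cats]
        )
        mism = (codes[:, None, :] != codes[None, :, :]).mean(axis=2)
        mat = mism.astype(float)
    elif method == "braycurtis_indicator":
        blocks = [pd.get_dummies(traits[c]).to_numpy(dtype=float) for c in cats]
        onehot = np.hstack(blocks)
        mat = squareform(pdist(onehot, metric="braycurtis"))
    else:
        raise ConfigurationError(f"unknown trait distance method {method!r}")
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=traits.index, columns=traits.index)


def _double_centre(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making ``d + c`` Euclidean-embeddable."""
    n = d.shape[0]
    delta1 = _double_centre(d**2)
    delta2 = _double_centre(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    eig = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(np.max(eig.real))


def pcoa(
    distances: pd.DataFrame | np.ndarray,
    correction: str = "additive",
    k_max: int = 2,
) -> TraitSpace:
    """Principal coordinate analysis of a distance matrix.

    The matrix is double-centred and eigendecomposed; when negative
    eigenvalues occur and ``correction="additive"``, the Cailliez constant
    is added to all off-diagonal distances and the decomposition is redone.
    At most ``k_max`` positive-eigenvalue axes are retained.
    """
    if correction not in ("none", "additive"):
        raise ConfigurationError(f"unknown PCoA correction {correction!r}")
    if k_max < 1:
        raise ConfigurationError("k_max must be >= 1")
    labels = (
        distances.index
        if isinstance(distances, pd.DataFrame)
        else pd.RangeIndex(len(distances))
    )
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DomainError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise DomainError("distance matrix must be symmetric")

    applied = "none"
    eigval, eigvec = np.linalg.eigh(_double_centre(d**2))
    scale = max(abs(eigval).max(), 1.0)
    if correction == "additive" and eigval.min() < -_EIG_TOL * scale:
        c = _cailliez_constant(d)
        if c > _EIG_TOL:
            d = d + c
            np.fill_diagonal(d, 0.0)
            applied = "additive"
            eigval, eigvec = np.linalg.eigh(_double_centre(d**2))

    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval).max(), 1.0)
    positive = eigval > _EIG_TOL * scale
    if not positive.any():
        raise DegenerateError("no positive eigenvalues: degenerate trait space")

    k = min(k_max, int(positive.sum()))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    quality = float(eigval[:k].sum() / eigval[positive].sum())
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return TraitSpace(
        coordinates=frame, eigenvalues=eigval, correction=applied, quality=quality
    )


def _coords_for(space: TraitSpace, taxa: Sequence) -> np.ndarray:
    missing = [t for t in taxa if t not in space.coordinates.index]
    if missing:
        raise DomainError(f"taxa absent from trait space: {missing}")
    return space.coordinates.loc[list(taxa)].to_numpy(dtype=float)


def fric(space: TraitSpace, present_taxa: Sequence) -> IndexValue:
    """Convex-hull volume of the present taxa on the retained axes.

    Flagged undefined when the number of species is <= the number of axes
    or the point configuration is degenerate (no full-dimensional hull).
    """
    taxa = list(present_taxa)
    s = len(taxa)
    if s <= space.n_axes:
        return IndexValue(np.nan, f"S<=axes (S={s}, axes={space.n_axes})")
    pts = _coords_for(space, taxa)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return IndexValue(np.nan, "degenerate hull")
    return IndexValue(float(hull.volume), None)


def _mst_edges(pts: np.ndarray, labels: Sequence) -> list[tuple[int, int, float]]:
    """Kruskal MST; ties broken by lexicographic taxon-pair order."""
    n = len(labels)
    d = squareform(pdist(pts))
    edges = sorted(
        (d[i, j], str(labels[i]), str(labels[j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out: list[tuple[int, int, float]] = []
    for w, _, _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            out.append((i, j, w))
            if len(out) == n - 1:
                break
    return out


def feve(space: TraitSpace, abundances: pd.Series) -> IndexValue:
    """Minimum-spanning-tree evenness of the abundance distribution.

    Branch weight EW = branch length / (w_i + w_j) on relative abundances;
    partial weights PEW = EW / sum(EW);
    FEve = (sum(min(PEW, 1/(S-1))) - 1/(S-1)) / (1 - 1/(S-1)).
    """
    w = abundances[abundances > 0]
    s = len(w)
    if s < 3:
        return IndexValue(np.nan, f"S<3 (S={s})")
    taxa = list(w.index)
    pts = _coords_for(space, taxa)
    rel = (w / w.sum()).to_numpy(dtype=float)
    edges = _mst_edges(pts, taxa)
    ew = np.array([length / (rel[i] + rel[j]) for i, j, length in edges])
    total = ew.sum()
    if total == 0:
        return IndexValue(np.nan, "all MST branch lengths zero")
    pew = ew / total
    thr = 1.0 / (s - 1)
    value = (np.minimum(pew, thr).sum() - thr) / (1.0 - thr)
    return IndexValue(float(value), None)


def fdiv(space: TraitSpace, abundances: pd.Series) -> IndexValue:
    """Abundance-weighted divergence from the hull-vertex centroid.

    With d_i the distance of species i to the centroid of the convex-hull
    vertices, dbar their unweighted mean, Dd = sum w_i (d_i - dbar) and
    D|d| = sum w_i |d_i - dbar|:  FDiv = (Dd + dbar) / (D|d| + dbar).
    """
    w = abundances[abundances > 0]
    s = len(w)
    if s < 3:
        return IndexValue(np.nan, f"S<3 (S={s})")
    taxa = list(w.index)
    pts = _coords_for(space, taxa)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return IndexValue(np.nan, "degenerate hull")
    centroid = pts[hull.vertices].mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    dbar = d.mean()
    rel = (w / w.sum()).to_numpy(dtype=float)
    delta_d = float(rel @ (d - dbar))
    delta_abs = float(rel @ np.abs(d - dbar))
    denom = delta_abs + dbar
    if denom == 0:
        return IndexValue(np.nan, "all species at the centroid")
    return IndexValue(float((delta_d + dbar) / denom), None)


def functional_diversity_table(
    community: CommunityMatrix | pd.DataFrame, space: TraitSpace
) -> pd.DataFrame:
    """Per-sample S, FRic, FEve and FDiv with undefined-reason flags."""
    abundance = as_abundance(community)
    rows = []
    for sample_id, row in abundance.iterrows():
        present = row[row > 0]
        r_fric = fric(space, list(present.index))
        r_feve = feve(space, present)
        r_fdiv = fdiv(space, present)
        flags = ";".join(
            f"{name}:{res.flag}"
            for name, res in (("fric", r_fric), ("feve", r_feve), ("fdiv", r_fdiv))
            if res.flag
        )
        rows.append(
            {
                "sample_id": sample_id,
                "S": int(len(present)),
                "fric": r_fric.value,
                "feve": r_feve.value,
                "fdiv": r_fdiv.value,
                "flags": flags,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def build_trait_space(
    traits: pd.DataFrame,
    method: str = "gower",
    correction: str = "additive",
    k_max: int = 2,
) -> TraitSpace:
    """Convenience: trait table -> distances -> corrected PCoA."""
    return pcoa(trait_distance(traits, method=method), correction=correction, k_max=k_max)
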