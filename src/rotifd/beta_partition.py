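"""Beta-diversity partitioning into replacement and richness difference.

For a pair of communities with shared richness ``a`` and unique richness
``b`` and ``c`` (presence-absence, Jaccard base):

    D        = (b + c) / (a + b + c)
    Repl     = 2 min(b, c) / (a + b + c)
    RichDiff = |b - c| / (a + b + c)

so that ``D = Repl + RichDiff`` holds exactly.  The quantitative variant
replaces a, b, c with the abundance components ``A = sum min(x, y)``,
``B = sum (x - min)`` and ``C = sum (y - min)`` (Ruzicka base).  Pairs are
also expressed as (Sim, Repl, RichDiff) triads with ``Sim = 1 - D``, which
sum to 1 and live on a triangle plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .datatypes import CommunityMatrix, as_abundance
from .errors import ConfigurationError, DegenerateError, DomainError, ValidationError

logger = logging.getLogger(__name__)

FAMILIES = ("podani-jaccard", "podani-ruzicka")


@dataclass
class BetaDecomposition:
    """Pairwise total dissimilarity split into its two components.

    ``total = replacement + richness_difference`` holds per pair to machine
    precision, and ``similarity = 1 - total``.
    """

    total: pd.DataFrame
    replacement: pd.DataFrame
    richness_difference: pd.DataFrame
    family: str

    @property
    def similarity(self) -> pd.DataFrame:
        sim = 1.0 - self.total
        np.fill_diagonal(sim.to_numpy(), 1.0)
        return sim

    def _tri_mean(self, frame: pd.DataFrame) -> float:
        m = frame.to_numpy()
        iu = np.triu_indices_from(m, k=1)
        return float(m[iu].mean())

    def means(self) -> dict[str, float]:
        """Lower-triangle means of each matrix."""
        return {
            "total": self._tri_mean(self.total),
            "replacement": self._tri_mean(self.replacement),
            "richness_difference": self._tri_mean(self.richness_difference),
            "similarity": 1.0 - self._tri_mean(self.total),
        }


@dataclass
class TriadTable:
    """Per-pair (Sim, Repl, RichDiff) triples; each sums to 1."""

    table: pd.DataFrame  # columns: sample_a, sample_b, sim, repl, richdiff
    mean_triple: tuple[float, float, float]


def braycurtis_matrix(community: CommunityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    Samples with zero total abundance are excluded with a warning.
    """
    x = as_abundance(community).astype(float)
    if len(x) < 2:
        raise DomainError("need at least two samples")
    totals = x.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        logger.warning("excluding zero-total samples from Bray-Curtis: %s", zero)
        x = x.loc[totals > 0]
        if len(x) < 2:
            raise DomainError("fewer than two samples with positive totals")
    mat = squareform(pdist(x.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(mat, index=x.index, columns=x.index)


def decompose_beta(
    community: CommunityMatrix | pd.DataFrame,
    quantitative: bool = False,
) -> BetaDecomposition:
    """Partition pairwise dissimilarity (Podani family).

    ``quantitative=False`` uses presence-absence on the Jaccard base;
    ``quantitative=True`` uses abundances on the Ruzicka base.
    """
    x = as_abundance(community).to_numpy(dtype=float)
    if x.size == 0:
        raise DomainError("empty community matrix")
    n = x.shape[0]
    if n < 2:
        raise DomainError("need at least two samples")
    labels = as_abundance(community).index

    if quantitative:
        mins = np.minimum(x[:, None, :], x[None, :, :])
        a = mins.sum(axis=2)
        row = x.sum(axis=1)
        b = row[:, None] - a
        c = row[None, :] - a
        family = "podani-ruzicka"
    else:
        p = (x > 0).astype(float)
        a = p @ p.T
        row = p.sum(axis=1)
        b = row[:, None] - a
        c = row[None, :] - a
        family = "podani-jaccard"

    denom = a + b + c
    if np.any(denom == 0):
        # pairs of empty communities: define all components as 0
        denom = np.where(denom == 0, 1.0, denom)
    total = (b + c) / denom
    repl = 2.0 * np.minimum(b, c) / denom
    rich = np.abs(b - c) / denom
    for m in (total, repl, rich):
        np.fill_diagonal(m, 0.0)

    def wrap(m: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(m, index=labels, columns=labels)

    return BetaDecomposition(
        total=wrap(total),
        replacement=wrap(repl),
        richness_difference=wrap(rich),
        family=family,
    )


def percent_contributions(decomposition: BetaDecomposition) -> tuple[float, float]:
    """Percent contributions of (replacement, richness difference) to mean D.

    Computed as mean(Repl) and mean(RichDiff) over the lower triangle,
    each divided by their sum; the two percentages add to 100.
    """
    m = decomposition.means()
    total = m["replacement"] + m["richness_difference"]
    if total == 0:
        raise DegenerateError("mean dissimilarity is zero; contributions undefined")
    repl_pct = 100.0 * m["replacement"] / total
    return repl_pct, 100.0 - repl_pct


def triad_table(decomposition: BetaDecomposition) -> TriadTable:
    """Per-pair (Sim, Repl, RichDiff) coordinates for triangle plots."""
    labels = decomposition.total.index
    tot = decomposition.total.to_numpy()
    rep = decomposition.replacement.to_numpy()
    ric = decomposition.richness_difference.to_numpy()
    iu, ju = np.triu_indices(len(labels), k=1)
    table = pd.DataFrame(
        {
            "sample_a": labels[iu],
            "sample_b": labels[ju],
            "sim": 1.0 - tot[iu, ju],
            "repl": rep[iu, ju],
            "richdiff": ric[iu, ju],
        }
    )
    mean_triple = (
        float(table["sim"].mean()),
        float(table["repl"].mean()),
        float(table["richdiff"].mean()),
    )
    return TriadTable(table=table, mean_triple=mean_triple)


@dataclass
class Dendrogram:
    """UPGMA tree over samples with a Newick serialization."""

    linkage_matrix: np.ndarray
    labels: list[str]
    newick: str


def _to_newick(node, labels: list[str]) -> str:
    def rec(n, parent_height: float) -> str:
        length = parent_height - n.dist / 2.0
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.10g}"
        left = rec(n.left, n.dist / 2.0)
        right = rec(n.right, n.dist / 2.0)
        return f"({left},{right}):{length:.10g}"

    if node.is_leaf():
        return f"{labels[node.id]}:0;"
    left = rec(node.left, node.dist / 2.0)
    right = rec(node.right, node.dist / 2.0)
    return f"({left},{right});"


def cluster_samples(
    distances: pd.DataFrame, linkage_method: str = "upgma"
) -> Dendrogram:
    """Agglomerative clustering of a pairwise distance matrix.

    UPGMA (average linkage) by default; merge heights are nondecreasing and
    the tree is serialized to Newick with ultrametric branch lengths
    (leaf depth = merge height / 2).
    """
    methods = {"upgma": "average", "single": "single", "complete": "complete"}
    if linkage_method not in methods:
        raise ConfigurationError(f"unknown linkage {linkage_method!r}")
    d = distances.to_numpy(dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if d.shape[0] < 2:
        raise DomainError("need at least two samples to cluster")
    labels = [str(x) for x in distances.index]
    z = linkage(squareform(d, checks=False), method=methods[linkage_method])
    newick = _to_newick(to_tree(z), labels)
    return Dendrogram(linkage_matrix=z, labels=labels, newick=newick)


def site_profiles(community: CommunityMatrix, aggregate: str = "mean") -> pd.DataFrame:
    """Month-aggregated abundance profile per site (site x taxon).

    Used for the between-site temporal decomposition; ``aggregate`` is the
    reduction across the months available at each site.
    """
    if aggregate not in ("mean", "sum"):
        raise ConfigurationError(f"unknown aggregate {aggregate!r}")
    grouped = community.abundance.groupby(community.meta["site"])
    return getattr(grouped, aggregate)()


def functional_beta(
    community: CommunityMatrix,
    traits: pd.DataFrame,
    category: str,
    quantitative: bool = False,
    by_site: bool = True,
) -> BetaDecomposition:
    """Beta decomposition on the modality x sample composition of one category."""
    from .functional_traits import composition_by_modality

    comp = composition_by_modality(community, traits, category)
    matrix = comp.absolute
    if by_site:
        matrix = matrix.groupby(community.meta["site"]).mean()
    return decompose_beta(matrix, quantitative=quantitative)
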