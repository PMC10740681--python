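import numpy as np
import pandas as pd
import pytest

from rotifd.beta_partition import (
    braycurtis_matrix,
    cluster_samples,
    decompose_beta,
    functional_beta,
    percent_contributions,
    site_profiles,
    triad_table,
)
from rotifd.errors import DegenerateError, DomainError, ValidationError

from conftest import random_abundance_pair


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def podani_jaccard_oracle(x: np.ndarray, y: np.ndarray):
    """Presence-absence decomposition from explicit set counts."""
    px, py = set(np.flatnonzero(x > 0)), set(np.flatnonzero(y > 0))
    a = len(px & py)
    b = len(px - py)
    c = len(py - px)
    n = a + b + c
    if n == 0:
        return 0.0, 0.0, 0.0
    return (b + c) / n, 2 * min(b, c) / n, abs(b - c) / n


def podani_ruzicka_oracle(x: np.ndarray, y: np.ndarray):
    a = float(np.minimum(x, y).sum())
    b = float((x - np.minimum(x, y)).sum())
    c = float((y - np.minimum(x, y)).sum())
    n = a + b + c
    if n == 0:
        return 0.0, 0.0, 0.0
    return (b + c) / n, 2 * min(b, c) / n, abs(b - c) / n


def upgma_oracle(d: np.ndarray):
    """Stepwise average-linkage agglomeration; returns sorted merge heights."""
    clusters = [[i] for i in range(len(d))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [d[a, b] for a in clusters[i] for b in clusters[j]]
                avg = float(np.mean(pairs))
                if best is None or avg < best[0]:
                    best = (avg, i, j)
        avg, i, j = best
        heights.append(avg)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestBrayCurtis:
    def test_identical_samples(self):
        x = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert braycurtis_matrix(x).loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_samples(self):
        x = pd.DataFrame([[5.0, 0.0], [0.0, 3.0]], index=["a", "b"])
        assert braycurtis_matrix(x).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_value(self):
        x = pd.DataFrame([[10.0, 0.0], [5.0, 5.0]], index=["a", "b"])
        assert braycurtis_matrix(x).loc["a", "b"] == pytest.approx(0.5)

    def test_zero_total_excluded(self):
        x = pd.DataFrame([[1.0, 1.0], [0.0, 0.0], [2.0, 0.0]], index=["a", "b", "c"])
        out = braycurtis_matrix(x)
        assert list(out.index) == ["a", "c"]


class TestDecompose:
    def test_identical_communities(self):
        x = pd.DataFrame([[1.0, 1.0, 0.0]] * 2, index=["u", "v"])
        d = decompose_beta(x)
        assert d.total.loc["u", "v"] == 0.0
        assert d.replacement.loc["u", "v"] == 0.0
        assert d.richness_difference.loc["u", "v"] == 0.0

    def test_full_replacement(self):
        # {A} vs {B}: a=0, b=1, c=1
        x = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["u", "v"])
        d = decompose_beta(x)
        assert d.total.loc["u", "v"] == pytest.approx(1.0)
        assert d.replacement.loc["u", "v"] == pytest.approx(1.0)
        assert d.richness_difference.loc["u", "v"] == pytest.approx(0.0)

    def test_nested_pair(self):
        # {A,B,C} vs {A}: a=1, b=2, c=0
        x = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 0.0, 0.0]], index=["u", "v"])
        d = decompose_beta(x)
        assert d.total.loc["u", "v"] == pytest.approx(2 / 3)
        assert d.replacement.loc["u", "v"] == pytest.approx(0.0)
        assert d.richness_difference.loc["u", "v"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("quantitative", [False, True])
    def test_additivity_and_oracle(self, quantitative):
        rng = np.random.default_rng(21)
        oracle = podani_ruzicka_oracle if quantitative else podani_jaccard_oracle
        for _ in range(200):
            frame = random_abundance_pair(rng)
            d = decompose_beta(frame, quantitative=quantitative)
            t = d.total.iloc[0, 1]
            r = d.replacement.iloc[0, 1]
            rd = d.richness_difference.iloc[0, 1]
            assert t == pytest.approx(r + rd, abs=1e-12)
            ot, orp, ord_ = oracle(frame.iloc[0].to_numpy(), frame.iloc[1].to_numpy())
            assert (t, r, rd) == pytest.approx((ot, orp, ord_), abs=1e-12)

    def test_site_swap_symmetry(self):
        rng = np.random.default_rng(5)
        frame = random_abundance_pair(rng)
        fwd = decompose_beta(frame)
        rev = decompose_beta(frame.iloc[::-1])
        assert fwd.total.iloc[0, 1] == pytest.approx(rev.total.iloc[0, 1])
        assert fwd.replacement.iloc[0, 1] == pytest.approx(rev.replacement.iloc[0, 1])
        assert fwd.richness_difference.iloc[0, 1] == pytest.approx(
            rev.richness_difference.iloc[0, 1]
        )

    def test_nestedness_limit(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            sup = rng.gamma(1, 5, 10)
            sub = sup.copy()
            sub[rng.random(10) < 0.5] = 0.0
            frame = pd.DataFrame([sup, sub], index=["sup", "sub"])
            d = decompose_beta(frame)
            assert d.replacement.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
            assert d.total.iloc[0, 1] == pytest.approx(
                d.richness_difference.iloc[0, 1], abs=1e-12
            )

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            decompose_beta(pd.DataFrame())


class TestContributions:
    def test_symmetric_case(self):
        x = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["u", "v"])
        d = decompose_beta(x)
        # Repl = 1, RichDiff = 0 for this pair
        repl, rich = percent_contributions(d)
        assert repl == pytest.approx(100.0)
        assert rich == pytest.approx(0.0)

    def test_printed_means(self):
        # independent arithmetic: 0.398 / (0.332 + 0.398) * 100
        repl_mean, rich_mean = 0.332, 0.398
        labels = pd.Index(["u", "v"])
        from rotifd.beta_partition import BetaDecomposition

        def mat(v):
            return pd.DataFrame(
                [[0.0, v], [v, 0.0]], index=labels, columns=labels
            )

        d = BetaDecomposition(
            total=mat(repl_mean + rich_mean),
            replacement=mat(repl_mean),
            richness_difference=mat(rich_mean),
            family="podani-jaccard",
        )
        repl_pct, rich_pct = percent_contributions(d)
        assert round(rich_pct, 2) == 54.52
        assert round(repl_pct, 2) == 45.48
        assert repl_pct + rich_pct == pytest.approx(100.0)

    def test_zero_mean_d(self):
        x = pd.DataFrame([[1.0, 1.0]] * 2, index=["u", "v"])
        with pytest.raises(DegenerateError):
            percent_contributions(decompose_beta(x))


class TestTriads:
    def test_identical_pair(self):
        x = pd.DataFrame([[1.0, 1.0]] * 2, index=["u", "v"])
        t = triad_table(decompose_beta(x)).table.iloc[0]
        assert (t["sim"], t["repl"], t["richdiff"]) == pytest.approx((1.0, 0.0, 0.0))

    def test_nested_pair_triple(self):
        x = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 0.0, 0.0]], index=["u", "v"])
        t = triad_table(decompose_beta(x)).table.iloc[0]
        assert (t["sim"], t["repl"], t["richdiff"]) == pytest.approx((1 / 3, 0.0, 2 / 3))

    def test_triples_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            frame = random_abundance_pair(rng)
            t = triad_table(decompose_beta(frame)).table
            sums = t[["sim", "repl", "richdiff"]].sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_mean_triple(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.gamma(1, 5, size=(6, 8)))
        x[x < 2] = 0.0
        x.index = [f"s{i}" for i in range(6)]
        t = triad_table(decompose_beta(x))
        assert t.mean_triple == pytest.approx(
            tuple(t.table[["sim", "repl", "richdiff"]].mean()), abs=1e-12
        )


class TestClustering:
    def test_two_samples(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        dendro = cluster_samples(d)
        assert dendro.linkage_matrix[0, 2] == pytest.approx(0.4)
        assert dendro.newick.count(",") == 1

    def test_nearest_pair_merges_first(self):
        labels = ["a", "b", "c"]
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=labels, columns=labels,
        )
        dendro = cluster_samples(d)
        assert dendro.linkage_matrix[0, 2] == pytest.approx(0.1)
        assert sorted(dendro.linkage_matrix[0, :2]) == [0, 1]

    def test_heights_match_oracle(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        frame = pd.DataFrame(d, index=[f"s{i}" for i in range(10)],
                             columns=[f"s{i}" for i in range(10)])
        dendro = cluster_samples(frame)
        heights = sorted(dendro.linkage_matrix[:, 2])
        assert heights == pytest.approx(upgma_oracle(d), abs=1e-9)

    def test_heights_nondecreasing_and_leaves(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(8, 2))
        from scipy.spatial.distance import pdist, squareform

        labels = [f"s{i}" for i in range(8)]
        frame = pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)
        dendro = cluster_samples(frame)
        assert (np.diff(dendro.linkage_matrix[:, 2]) >= -1e-12).all()
        for label in labels:
            assert label in dendro.newick

    def test_newick_parses_ultrametric(self):
        # round-trip the serialization through an independent parser
        import io as _io

        from Bio import Phylo

        rng = np.random.default_rng(23)
        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist, squareform

        labels = [f"s{i}" for i in range(6)]
        frame = pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)
        dendro = cluster_samples(frame)
        tree = Phylo.read(_io.StringIO(dendro.newick), "newick")
        depths = tree.depths()
        leaf_depths = [v for k, v in depths.items() if k.name in labels]
        root_height = dendro.linkage_matrix[-1, 2] / 2.0
        assert leaf_depths == pytest.approx([root_height] * 6, abs=1e-9)

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0.0, 0.5], [0.6, 0.0]])
        with pytest.raises(ValidationError):
            cluster_samples(d)


class TestFunctionalVsTaxonomic:
    def test_functional_beta_lower(self):
        import rotifd

        ds = rotifd.generate_dataset(master_seed=1)
        taxonomic = decompose_beta(ds.community.abundance).means()["total"]
        from rotifd.functional_traits import TRAIT_CATEGORIES

        functional = np.mean(
            [
                functional_beta(ds.community, ds.traits, cat, by_site=False)
                .means()["total"]
                for cat in TRAIT_CATEGORIES
            ]
        )
        assert functional < taxonomic

    def test_site_profiles_shape(self):
        import rotifd

        ds = rotifd.generate_dataset(master_seed=3, n_sites=4, n_months=3)
        profiles = site_profiles(ds.community)
        assert profiles.shape == (4, ds.config.n_species)
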