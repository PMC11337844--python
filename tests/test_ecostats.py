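import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import pdist, squareform

from asimm.ecostats import (
    DissimilarityMatrix,
    anosim,
    bray_curtis,
    compare_richness,
    jaccard,
    pcoa,
    richness,
    shared_genus_fraction,
    upgma,
)
from asimm.io import CountTable


def table_from(arr, samples=None):
    arr = np.asarray(arr)
    return CountTable(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=samples or [f"s{j}" for j in range(arr.shape[1])],
        )
    )


def random_table(seed, n_features=40, n_samples=8):
    rng = np.random.default_rng(seed)
    return table_from(rng.integers(0, 20, size=(n_features, n_samples)))


class TestDissimilarities:
    def test_identical_samples_zero(self):
        t = table_from([[5, 5], [2, 2], [0, 0]])
        assert jaccard(t).values[0, 1] == 0.0
        assert bray_curtis(t).values[0, 1] == 0.0

    def test_disjoint_presence_is_one(self):
        t = table_from([[5, 0], [3, 0], [0, 2]])
        assert jaccard(t).values[0, 1] == 1.0
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_jaccard_set_arithmetic(self):
        # A = {g0,g1,g2}, B = {g1,g2,g3}: 1 - 2/4
        t = table_from([[1, 0], [1, 1], [1, 1], [0, 1]])
        assert jaccard(t).values[0, 1] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self):
        t = table_from([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            jaccard(t)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_pairwise(self, seed):
        t = random_table(seed)
        ours = jaccard(t).condensed()
        ref = pdist((t.data.to_numpy() > 0).T, metric="jaccard")
        assert np.allclose(ours, ref, atol=1e-12)
        relab = (t.data / t.data.sum(axis=0)).T.to_numpy()
        assert np.allclose(bray_curtis(t).condensed(),
                           pdist(relab, metric="braycurtis"), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_jaccard_triangle_inequality(self, seed):
        d = jaccard(random_table(seed)).values
        n = len(d)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_matrix_invariants(self):
        d = bray_curtis(random_table(3))
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)
        assert ((d.values >= 0) & (d.values <= 1)).all()


class TestAnosim:
    def _separated(self):
        # two groups with every between-group distance above every
        # within-group distance
        vals = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.2],
                [0.8, 0.95, 0.2, 0.0],
            ]
        )
        return DissimilarityMatrix(vals, ["a1", "a2", "b1", "b2"])

    def test_complete_separation_gives_r_one(self):
        res = anosim(self._separated(), ["A", "A", "B", "B"], seed=0)
        assert res.r == pytest.approx(1.0)
        assert 0 < res.p <= 1

    def test_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        t = random_table(5, n_samples=10)
        d = bray_curtis(t)
        labels = ["A"] * 5 + ["B"] * 5
        ours = anosim(d, labels, n_permutations=99, seed=0)
        ref = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(d.values, d.ids), grouping=labels,
            permutations=0,
        )
        assert ours.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_rank_based_invariance_under_monotone_transform(self):
        t = random_table(7, n_samples=10)
        d = bray_curtis(t)
        labels = ["A", "B"] * 5
        base = anosim(d, labels, n_permutations=49, seed=1)
        transformed = DissimilarityMatrix(np.sqrt(d.values), d.ids)
        trans = anosim(transformed, labels, n_permutations=49, seed=1)
        assert base.r == pytest.approx(trans.r, abs=1e-12)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(11)
        t = random_table(11, n_samples=12)
        d = bray_curtis(t)
        rs = []
        for i in range(200):
            labels = rng.permutation(["A"] * 6 + ["B"] * 6)
            rs.append(anosim(d, labels, n_permutations=0, seed=i).r)
        assert abs(np.mean(rs)) < 0.05

    def test_singleton_group_rejected(self):
        d = self._separated()
        with pytest.raises(ValueError, match="singleton"):
            anosim(d, ["A", "A", "A", "B"], seed=0)

    def test_deterministic_p_value(self):
        d = self._separated()
        labels = ["A", "A", "B", "B"]
        p1 = anosim(d, labels, seed=3).p
        p2 = anosim(d, labels, seed=3).p
        assert p1 == p2


class TestPcoa:
    def test_three_equidistant_points(self):
        vals = np.full((3, 3), 0.6)
        np.fill_diagonal(vals, 0.0)
        res = pcoa(DissimilarityMatrix(vals, ["a", "b", "c"]), k=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)
        assert res.eigenvalues[0] > 0

    def test_collinear_configuration_one_axis(self):
        x = np.array([0.0, 0.1, 0.25, 0.6, 0.9])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DissimilarityMatrix(d, list("abcde")), k=1)
        assert res.proportion_explained[0] > 0.99

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 0.3, size=(6, 3))
        d = squareform(pdist(pts))
        res = pcoa(DissimilarityMatrix(d, [f"s{i}" for i in range(6)]), k=3)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_k_beyond_positive_eigenvalues_rejected(self):
        x = np.array([0.0, 0.2, 0.5])
        d = np.abs(x[:, None] - x[None, :])  # rank-1 configuration
        with pytest.raises(ValueError, match="positive eigenvalue"):
            pcoa(DissimilarityMatrix(d, list("abc")), k=2)

    def test_negative_eigenvalues_reported(self):
        d = jaccard(random_table(13, n_samples=10))
        res = pcoa(d, k=2)
        assert len(res.eigenvalues) == 10
        # Jaccard is generally non-Euclidean: negatives are kept visible
        assert res.eigenvalues.min() < res.eigenvalues.max()


class TestUpgma:
    def test_two_samples_forced_tree(self):
        d = DissimilarityMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
        assert upgma(d) == "(A:0.2,B:0.2);"

    def test_three_samples_forced_merge_order(self):
        vals = np.array(
            [[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]]
        )
        d = DissimilarityMatrix(vals, ["A", "B", "C"])
        assert upgma(d) == "((A:0.1,B:0.1):0.3,C:0.4);"

    def test_deterministic_tie_breaking(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 0.0)
        d = DissimilarityMatrix(vals, ["b", "c", "a"])
        assert upgma(d) == upgma(d)
        assert upgma(d).startswith("((a:")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cophenetic_matches_scipy_average_linkage(self, seed):
        dendropy = pytest.importorskip("dendropy")
        t = random_table(seed, n_samples=7)
        d = bray_curtis(t)
        tree = dendropy.Tree.get(data=upgma(d), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in tree.taxon_namespace}
        ours = np.array(
            [
                pdm.distance(taxa[a], taxa[b])
                for i, a in enumerate(d.ids)
                for b in d.ids[i + 1:]
            ]
        )
        ref = cophenet(average(d.condensed()))
        assert np.allclose(ours, ref, atol=1e-10)

    def test_ultrametric_output(self):
        dendropy = pytest.importorskip("dendropy")
        d = bray_curtis(random_table(9, n_samples=6))
        tree = dendropy.Tree.get(data=upgma(d), schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.allclose(depths, depths[0], atol=1e-10)


class TestRichness:
    def test_counts_nonzero_features(self):
        t = table_from([[1, 0], [2, 0], [3, 1], [0, 0], [4, 2]])
        assert richness(t).tolist() == [4, 2]

    def test_identical_groups_p_one(self):
        res = compare_richness([10, 10, 10], [10, 10, 10])
        assert res.p == 1.0

    def test_separated_groups_significant(self):
        res = compare_richness([10, 11, 12], [20, 21, 22])
        assert res.p < 0.01

    def test_matches_scipy_welch(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(1)
        a, b = rng.normal(50, 5, 8), rng.normal(55, 9, 6)
        ours = compare_richness(a, b)
        ref = ttest_ind(a, b, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_richness([1], [2, 3])


class TestSharedGenusFraction:
    def test_identical_samples(self):
        t = table_from([[1, 1, 1], [2, 2, 2]])
        res = shared_genus_fraction(t)
        assert (res.fractions == 1.0).all()
        assert res.mean == 1.0 and res.sd == 0.0

    def test_disjoint_samples(self):
        t = table_from([[1, 0], [0, 1]])
        res = shared_genus_fraction(t)
        assert res.mean == 0.0

    def test_worked_example(self):
        # 3 samples sharing a 4-genus core, richness (8, 10, 16)
        n = 26
        arr = np.zeros((n, 3), dtype=int)
        arr[:4, :] = 1            # core in all samples
        arr[4:8, 0] = 1           # sample 0: richness 8
        arr[8:14, 1] = 1          # sample 1: richness 10
        arr[14:26, 2] = 1         # sample 2: richness 16
        res = shared_genus_fraction(table_from(arr))
        assert res.core_size == 4
        assert res.fractions.tolist() == [0.5, 0.4, 0.25]
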