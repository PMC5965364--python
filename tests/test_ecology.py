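"""Diversity, distances, ordination, clustering, k-mer distances, tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from archaeome import ecology, profiler, simkit
from archaeome.ecology import DistanceMatrix
from conftest import make_reads


def _profile(sid, species_ab):
    lineages = {
        sp: {"kingdom": "bacteria", "class": f"c{sp[0]}", "family": f"f{sp}",
             "genus": f"g{sp}", "species": sp}
        for sp in species_ab
    }
    return profiler.AbundanceProfile(
        sid, profiler._aggregate_ranks(species_ab, lineages), 100, lineages
    )


class TestShannon:
    def test_single_taxon_zero(self):
        assert ecology.shannon({"a": 1.0}) == pytest.approx(0.0)

    def test_uniform_four_taxa(self):
        assert ecology.shannon([0.25] * 4) == pytest.approx(np.log(4), abs=1e-9)

    def test_closed_form_value(self):
        assert ecology.shannon([0.5, 0.3, 0.2]) == pytest.approx(1.0297, abs=1e-4)

    def test_empty_profile_undefined(self):
        assert ecology.shannon({}) is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10),
           st.integers(0, 1000))
    def test_permutation_invariant_and_uniform_maximal(self, raw, seed):
        p = np.array(raw) / np.sum(raw)
        h = ecology.shannon(p)
        perm = np.random.default_rng(seed).permutation(p)
        assert ecology.shannon(perm) == pytest.approx(h, abs=1e-9)
        assert h <= np.log(len(p)) + 1e-12


class TestDistanceMatrix:
    def test_identical_profiles_at_zero_distance(self):
        p = _profile("a", {"x": 0.6, "y": 0.4})
        q = _profile("b", {"x": 0.6, "y": 0.4})
        for metric in ("jaccard", "bray_curtis"):
            D = ecology.distance_matrix([p, q], "species", metric)
            assert D.data[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_jaccard_set_arithmetic(self):
        p = _profile("a", {"x": 0.5, "y": 0.5})
        q = _profile("b", {"y": 0.5, "z": 0.5})
        D = ecology.distance_matrix([p, q], "species", "jaccard")
        assert D.data[0, 1] == pytest.approx(1 - 1 / 3, abs=1e-9)

    def test_bray_curtis_direct_evaluation(self):
        p = _profile("a", {"x": 0.6, "y": 0.4})
        q = _profile("b", {"x": 0.2, "y": 0.8})
        D = ecology.distance_matrix([p, q], "species", "bray_curtis")
        assert D.data[0, 1] == pytest.approx(0.4, abs=1e-9)

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.5], [0.4, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.1, 0.5], [0.5, 0.0]]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_jaccard_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        profs = []
        for i in range(3):
            n = rng.integers(2, 6)
            taxa = rng.choice(10, size=n, replace=False)
            ab = rng.dirichlet(np.ones(n))
            profs.append(_profile(f"s{i}", {f"t{t}": a for t, a in zip(taxa, ab)}))
        D = ecology.distance_matrix(profs, "species", "jaccard").data
        for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestPcoa:
    def test_collinear_points_hand_oracle(self):
        # samples at positions 0, 1, 2 on a line
        pos = np.array([[0.0], [1.0], [2.0]])
        D = DistanceMatrix(["a", "b", "c"], squareform(pdist(pos)))
        res = ecology.pcoa(D)
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-9)
        axis1 = res.coordinates[:, 0]
        assert np.allclose(np.abs(axis1), [1, 0, 1], atol=1e-9)
        assert axis1[0] == pytest.approx(-axis1[2], abs=1e-9)

    def test_equals_pca_on_euclidean_distances(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        D = DistanceMatrix([f"s{i}" for i in range(12)], squareform(pdist(X)))
        co = ecology.pcoa(D).coordinates
        sc = ecology.pca(X).coordinates
        k = min(co.shape[1], sc.shape[1])
        _, _, disparity = procrustes(co[:, :k], sc[:, :k])
        assert disparity < 1e-8

    def test_agrees_with_skbio_reference(self):
        import warnings
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        d = squareform(pdist(X))
        ours = ecology.pcoa(DistanceMatrix([f"s{i}" for i in range(8)], d))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio_pcoa(SkbioDM(d), method="eigh")
        ref_coords = ref.samples.values[:, : ours.coordinates.shape[1]]
        _, _, disparity = procrustes(ours.coordinates, ref_coords)
        assert disparity < 1e-8

    def test_equidistant_simplex_has_equal_eigenvalues(self):
        D = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        res = ecology.pcoa(D)
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], abs=1e-9)

    def test_non_euclidean_negative_eigenvalues_reported(self):
        d = np.array(
            [[0, 1, 1, 1.9], [1, 0, 1, 1], [1, 1, 0, 1], [1.9, 1, 1, 0]]
        )
        res = ecology.pcoa(DistanceMatrix(list("abcd"), d))
        assert len(res.negative_eigenvalues) >= 1
        assert res.coordinates.shape[1] == len(res.eigenvalues)


class TestPca:
    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(5)
        row = rng.normal(size=4)
        X = np.vstack([row, row, rng.normal(size=4)])
        res = ecology.pca(X)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-10)

    def test_rank_one_data_single_component(self):
        u = np.outer([1.0, 2.0, 3.0], [1.0, -1.0, 0.5])
        res = ecology.pca(u)
        assert res.eigenvalues[0] > 1e-9
        assert np.allclose(res.eigenvalues[1:], 0, atol=1e-9)

    def test_constant_matrix_flagged(self):
        res = ecology.pca(np.ones((3, 4)))
        assert res.coordinates.shape[1] == 0


class TestHierarchicalCluster:
    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.1, (4, 3)), rng.normal(5, 0.1, (4, 3))])
        ids = [f"s{i}" for i in range(8)]
        D = DistanceMatrix(ids, squareform(pdist(X)))
        tree = ecology.hierarchical_cluster(D, "average")
        labels = tree.cut(2)
        g0 = {labels[f"s{i}"] for i in range(4)}
        g1 = {labels[f"s{i}"] for i in range(4, 8)}
        assert len(g0) == 1 and len(g1) == 1 and g0 != g1

    def test_zero_distance_pair_merges_first(self):
        d = np.array([[0, 0, 0.9], [0, 0, 0.9], [0.9, 0.9, 0]], dtype=float)
        tree = ecology.hierarchical_cluster(DistanceMatrix(list("abc"), d))
        assert set(tree.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 3))
        ids = [f"s{i}" for i in range(6)]
        D = squareform(pdist(X))
        t1 = ecology.hierarchical_cluster(DistanceMatrix(ids, D))
        perm = [3, 1, 5, 0, 2, 4]
        D2 = D[np.ix_(perm, perm)]
        t2 = ecology.hierarchical_cluster(
            DistanceMatrix([ids[i] for i in perm], D2)
        )
        assert t1.to_newick() == t2.to_newick()

    def test_newick_parses_with_all_leaves(self):
        from skbio import TreeNode
        import io

        d = squareform(pdist(np.random.default_rng(8).normal(size=(5, 2))))
        tree = ecology.hierarchical_cluster(DistanceMatrix([f"s{i}" for i in range(5)], d))
        parsed = TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == {f"s{i}" for i in range(5)}

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            ecology.hierarchical_cluster(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestKmerDistance:
    def test_identical_read_sets_at_zero(self):
        reads = make_reads(["ACGTACGTACGTACG", "TTGGCCAATTGGCCA"])
        D = ecology.kmer_distance({"a": reads, "b": reads}, k=5)
        assert D.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reverse_complement_invariance(self):
        from archaeome._seq import revcomp

        seqs = ["ACGTACGTACGTACG", "GGGTTTAAACCCGGG"]
        D = ecology.kmer_distance(
            {"a": make_reads(seqs), "b": make_reads([revcomp(s) for s in seqs])}, k=5
        )
        assert D.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_short_reads_skipped_and_empty_sample_undefined(self):
        D = ecology.kmer_distance(
            {"a": make_reads(["ACGTACGTACGT"]), "b": make_reads(["ACG"])}, k=10
        )
        assert np.isnan(D.data[0, 1])

    def test_between_genome_distance_exceeds_within(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g1 = simkit.random_sequence(4000, rng)
            g2 = simkit.random_sequence(4000, rng)
            def sample_reads(g, s):
                frags = simkit.simulate_fragments(g, 150, (60, 0, 25), seed=s)
                return make_reads([g[a : a + l] for a, l, _ in frags])
            D = ecology.kmer_distance(
                {
                    "a1": sample_reads(g1, seed * 3),
                    "a2": sample_reads(g1, seed * 3 + 1),
                    "b": sample_reads(g2, seed * 3 + 2),
                },
                k=10,
            )
            within = D.data[0, 1]
            between = (D.data[0, 2] + D.data[1, 2]) / 2
            wins += between > within
        assert wins >= 17


class TestGroupTest:
    def test_identical_groups_centered_statistic(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = ["a"] * 3 + ["b"] * 3
        stat, p = ecology.group_test(vals, labels, "t")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
        labels = ["a"] * 30 + ["b"] * 30
        for test in ("t", "wilcoxon"):
            _, p = ecology.group_test(vals, labels, test)
            assert p < 0.001

    def test_anova_null_pvalues_uniform_under_permutation(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=30)
        pvals = []
        for _ in range(500):
            labels = rng.permutation(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
            _, p = ecology.group_test(vals, labels, "anova")
            pvals.append(p)
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_manova_runs_on_multivariate_groups(self):
        rng = np.random.default_rng(11)
        vals = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(2, 1, (15, 3))])
        labels = ["a"] * 15 + ["b"] * 15
        stat, p = ecology.group_test(vals, labels, "manova")
        assert p < 0.01

    def test_degenerate_groups_named_in_error(self):
        with pytest.raises(ValueError, match="two groups"):
            ecology.group_test([1.0, 2.0], ["a", "a"], "t")
        with pytest.raises(ValueError, match="two samples per group"):
            ecology.group_test([1.0, 2.0, 3.0], ["a", "a", "b"], "anova")

    def test_tukey_hsd_after_anova(self):
        rng = np.random.default_rng(12)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10),
                               rng.normal(0, 1, 10)])
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        table = ecology.tukey_hsd(vals, labels)
        assert len(table) == 3  # all pairwise comparisons
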