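"""PERMANOVA, PERMDISP, PCoA and UPGMA against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from commdecay.core_io import DistanceMatrix
from commdecay.exceptions import DesignError
from commdecay.multivariate import (
    centroid_distances,
    hac_average_linkage,
    merge_heights,
    pairwise_permanova,
    pcoa,
    permanova,
    permdisp,
)
from conftest import random_dissimilarity


def euclidean_matrix(points: np.ndarray, labels=None) -> DistanceMatrix:
    labels = labels or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(labels, squareform(pdist(points)), "dissimilarity")


class TestPermanova:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_univariate_euclidean_equals_classical_anova_f(self, seed):
        """On 1-D data with Euclidean distance, pseudo-F is the ANOVA F."""
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 7, size=rng.integers(2, 5))
        values = [rng.normal(g, 1.0, size=n) for g, n in enumerate(sizes)]
        flat = np.concatenate(values)[:, None]
        groups = {
            f"p{i}": f"g{g}"
            for i, g in enumerate(np.repeat(np.arange(len(sizes)), sizes))
        }
        d = euclidean_matrix(flat)
        res = permanova(d, groups, n_perm=9, seed=0)
        f_classic = f_oneway(*values).statistic
        assert res.pseudo_F == pytest.approx(f_classic, abs=1e-10)

    def test_ss_decomposition_and_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        d = random_dissimilarity(9, rng)
        groups = {l: "g" + str(i % 3) for i, l in enumerate(d.labels)}
        res = permanova(d, groups, n_perm=19, seed=1)
        assert res.ss_between + res.ss_within == pytest.approx(res.ss_total)
        shuffled = d.submatrix(list(reversed(d.labels)))
        res2 = permanova(shuffled, groups, n_perm=19, seed=1)
        assert res2.pseudo_F == pytest.approx(res.pseudo_F)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        d = random_dissimilarity(10, rng)
        groups = {l: "g" + str(i % 2) for i, l in enumerate(d.labels)}
        res = permanova(d, groups, n_perm=9, seed=0)
        dm = skbio.DistanceMatrix(d.values, ids=d.labels)
        ref = skbio.stats.distance.permanova(
            dm, grouping=[groups[l] for l in d.labels], permutations=9
        )
        assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_sampled_p_within_binomial_error_of_exhaustive(self):
        """At N=6 all 720 relabelings are enumerable; the sampled p agrees."""
        rng = np.random.default_rng(3)
        pts = np.concatenate([rng.normal(0, 1, 3), rng.normal(1.5, 1, 3)])[:, None]
        d = euclidean_matrix(pts)
        codes = np.array([0, 0, 0, 1, 1, 1])
        groups = {l: f"g{c}" for l, c in zip(d.labels, codes)}
        f_obs = permanova(d, groups, n_perm=1, seed=0).pseudo_F

        d2 = d.values**2

        def pseudo_f(assign):
            n = len(assign)
            ss_t = d2.sum() / (2 * n)
            ss_w = 0.0
            for g in (0, 1):
                idx = np.flatnonzero(np.asarray(assign) == g)
                ss_w += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
            return (ss_t - ss_w) / (ss_w / (n - 2))

        exhaustive = [
            pseudo_f([codes[j] for j in perm]) for perm in itertools.permutations(range(6))
        ]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in exhaustive])

        res = permanova(d, groups, n_perm=999, seed=11)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_perm - p_exact) < 4 * se + 2 / 999

    def test_single_group_is_design_error(self):
        d = random_dissimilarity(4, np.random.default_rng(0))
        with pytest.raises(DesignError):
            permanova(d, {l: "same" for l in d.labels}, n_perm=9, seed=0)


class TestPairwisePermanova:
    def test_three_groups_give_three_tests_with_multiplier(self):
        rng = np.random.default_rng(5)
        d = random_dissimilarity(9, rng)
        groups = {l: "g" + str(i % 3) for i, l in enumerate(d.labels)}
        results = pairwise_permanova(d, groups, n_perm=19, seed=0)
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_perm * 3))

    def test_identical_clouds_do_not_reject(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(16, 3))
        d = euclidean_matrix(pts)
        groups = {l: "g" + str(i % 2) for i, l in enumerate(d.labels)}
        results = pairwise_permanova(d, groups, n_perm=199, seed=4)
        assert results[0].p_perm > 0.05
        assert results[0].p_adjusted >= results[0].p_perm


class TestPermdisp:
    def test_equal_centroid_distances_give_f_zero(self):
        # two groups of two points, each pair 2 apart: every centroid distance 1
        m = np.array(
            [
                [0, 2, 5, 5],
                [2, 0, 5, 5],
                [5, 5, 0, 2],
                [5, 5, 2, 0],
            ],
            dtype=float,
        )
        d = DistanceMatrix(["a1", "a2", "b1", "b2"], m, "dissimilarity")
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = permdisp(d, groups, n_perm=19, seed=0)
        assert res.F == 0.0
        assert res.p_anova == 1.0

    def test_type_one_error_calibrated_on_spherical_clouds(self):
        """Two groups from one spherical cloud: rejection near nominal 5%."""
        rng = np.random.default_rng(0)
        rej = 0
        n_rep = 200
        groups = {f"p{i}": "A" if i < 20 else "B" for i in range(40)}
        for _ in range(n_rep):
            pts = rng.normal(size=(40, 4))
            res = permdisp(euclidean_matrix(pts), groups, n_perm=99,
                           seed=int(rng.integers(2**31)))
            rej += res.p_perm <= 0.05
        assert rej / n_rep <= 0.08

    def test_power_against_inflated_dispersion(self):
        """One group scaled x3: detected in >=80% of 200 replicates."""
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 200
        groups = {f"p{i}": "A" if i < 20 else "B" for i in range(40)}
        for _ in range(n_rep):
            pts = rng.normal(size=(40, 4))
            pts[20:] *= 3.0
            res = permdisp(euclidean_matrix(pts), groups, n_perm=99,
                           seed=int(rng.integers(2**31)))
            hits += res.p_perm <= 0.05
        assert hits / n_rep >= 0.80

    def test_group_of_one_is_design_error(self):
        d = random_dissimilarity(5, np.random.default_rng(2))
        groups = dict(zip(d.labels, ["A", "A", "A", "A", "B"]))
        with pytest.raises(DesignError):
            permdisp(d, groups, n_perm=9, seed=0)

    def test_centroid_distances_nonnegative_on_noneuclidean_input(self):
        rng = np.random.default_rng(3)
        d = random_dissimilarity(12, rng)  # generally non-Euclidean
        groups = {l: "g" + str(i % 2) for i, l in enumerate(d.labels)}
        z = centroid_distances(d, groups)
        assert (z >= 0).all()


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 2))
        d = euclidean_matrix(pts)
        res = pcoa(d, n_axes=2)
        fitted = squareform(pdist(res.coordinates))
        assert np.allclose(fitted, d.values, atol=1e-8)
        assert res.stress1 < 1e-8
        # Euclidean input: negative eigenvalues are numerically zero
        assert res.eigenvalues.min() > -1e-8 * res.eigenvalues.max()

    def test_equidistant_points_form_simplex(self):
        n = 5
        m = np.ones((n, n)) - np.eye(n)
        d = DistanceMatrix([f"p{i}" for i in range(n)], m, "dissimilarity")
        res = pcoa(d, n_axes=n)
        positive = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(positive) == n - 1
        assert np.allclose(positive, positive[0], rtol=1e-8)

    def test_duplicated_point_is_coincident(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        res = pcoa(euclidean_matrix(pts), n_axes=2)
        assert np.allclose(res.coordinates[1], res.coordinates[2], atol=1e-10)

    def test_all_zero_matrix_degenerates_to_origin(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)), "dissimilarity")
        res = pcoa(d, n_axes=2)
        assert np.allclose(res.coordinates, 0.0)
        assert np.isnan(res.goodness)

    def test_axes_ordered_by_eigenvalue(self):
        d = random_dissimilarity(8, np.random.default_rng(6))
        res = pcoa(d, n_axes=3)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


def brute_force_upgma(labels, values):
    """Naive UPGMA over explicit leaf sets, for cross-checking."""
    clusters = [frozenset([i]) for i in range(len(labels))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            mean = np.mean([values[i][j] for i in a for j in b])
            name = tuple(sorted((min(labels[i] for i in a), min(labels[j] for j in b))))
            if best is None or (mean, name) < (best[0], best[1]):
                best = (mean, name, a, b)
        mean, _, a, b = best
        merges.append((mean, frozenset(a | b)))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


class TestUpgma:
    def test_hand_worked_three_points(self):
        # points 0, 1, 10 on a line: merge {0,1} at 1, then at (9+10)/2 = 9.5
        pts = np.array([[0.0], [1.0], [10.0]])
        root, linkage = hac_average_linkage(euclidean_matrix(pts, ["x", "y", "z"]))
        assert linkage[0, 2] == pytest.approx(1.0)
        assert linkage[1, 2] == pytest.approx(9.5)
        assert root.merge_height == pytest.approx(9.5)

    def test_identical_leaves_merge_first_at_zero(self):
        m = np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]], dtype=float)
        d = DistanceMatrix(["a", "b", "c"], m, "dissimilarity")
        _, linkage = hac_average_linkage(d)
        assert linkage[0, 2] == 0.0
        assert set(linkage[0, :2]) == {0.0, 1.0}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dissimilarity(6, rng)
        _, linkage = hac_average_linkage(d)
        expected = brute_force_upgma(d.labels, d.values)
        assert len(expected) == linkage.shape[0]
        for row, (mean, members) in zip(linkage, expected):
            assert row[2] == pytest.approx(mean)
            assert row[3] == len(members)

    def test_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        rng = np.random.default_rng(9)
        d = random_dissimilarity(7, rng)
        _, ours = hac_average_linkage(d)
        ref = scipy_linkage(d.condensed(), method="average")
        assert np.allclose(np.sort(ours[:, 2]), np.sort(ref[:, 2]), atol=1e-10)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(12)
        d = random_dissimilarity(10, rng)
        root, linkage = hac_average_linkage(d)
        assert (np.diff(linkage[:, 2]) >= -1e-12).all()
        heights = merge_heights(root)
        assert max(heights) == pytest.approx(root.merge_height)

    def test_newick_export_parses(self):
        import io

        from Bio import Phylo

        d = random_dissimilarity(5, np.random.default_rng(1))
        root, _ = hac_average_linkage(d)
        tree = Phylo.read(io.StringIO(root.newick()), "newick")
        assert tree.count_terminals() == 5
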