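"""Disparity metrics, bootstrap/rarefaction resampling, permutation tests,
NPMANOVA (cross-checked against an independent PERMANOVA implementation)
and snake-centroid augmentation."""

import math
from itertools import combinations

import numpy as np
import pytest

import squamorph as sq
from squamorph.resampling import DegenerateGeometryError, _pseudo_f_from_d2


class TestSumOfVariances:
    def test_identical_rows_give_zero(self):
        assert sq.sum_of_variances(np.ones((5, 3))) == 0.0

    def test_hand_oracle_square(self):
        pts = np.array([[0, 0], [2, 0], [0, 2], [2, 2]], float)
        assert sq.sum_of_variances(pts) == pytest.approx(8 / 3)

    def test_rotation_invariance(self, rng):
        pts = rng.normal(0, 1, (10, 3))
        q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
        assert sq.sum_of_variances(pts @ q) == pytest.approx(
            sq.sum_of_variances(pts))

    def test_centroid_distance_identity(self, rng):
        for _ in range(100):
            pts = rng.normal(0, 1, (rng.integers(2, 12), rng.integers(1, 6)))
            d2 = ((pts - pts.mean(axis=0)) ** 2).sum()
            assert sq.sum_of_variances(pts) == pytest.approx(
                d2 / (pts.shape[0] - 1))

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            sq.sum_of_variances(np.ones((1, 3)))


class TestHullVolume:
    def test_unit_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert sq.hull_volume(pts) == pytest.approx(1 / 6, abs=1e-12)

    def test_interior_point_leaves_volume_unchanged(self, rng):
        pts = rng.normal(0, 1, (10, 3))
        v0 = sq.hull_volume(pts)
        interior = pts.mean(axis=0)[None, :]
        assert sq.hull_volume(np.vstack([pts, interior])) == pytest.approx(v0)

    def test_monotone_under_point_addition(self, rng):
        for _ in range(100):
            pts = rng.normal(0, 1, (8, 3))
            v0 = sq.hull_volume(pts)
            extra = rng.normal(0, 2, (1, 3))
            assert sq.hull_volume(np.vstack([pts, extra])) >= v0 - 1e-12

    def test_scales_with_cube_of_isotropic_scaling(self, rng):
        pts = rng.normal(0, 1, (12, 3))
        assert sq.hull_volume(3.0 * pts) == pytest.approx(
            27.0 * sq.hull_volume(pts))

    def test_too_few_points_is_explicit_error(self):
        with pytest.raises(DegenerateGeometryError):
            sq.hull_volume(np.eye(3))

    def test_coplanar_points_are_explicit_error(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 2, 0]],
                       float)
        with pytest.raises(DegenerateGeometryError):
            sq.hull_volume(pts)


class TestBootstrap:
    def test_degenerate_group_gives_zero_ci(self):
        est = sq.bootstrap_ci(np.ones((6, 2)), "sum_of_variances",
                              n_boot=50, seed=0)
        assert est.value == 0.0
        assert (est.ci_low, est.ci_high) == (0.0, 0.0)

    def test_ci_bounds_within_iterate_range_and_reproducible(self, rng):
        rows = rng.normal(0, 1, (15, 4))
        a = sq.bootstrap_ci(rows, "sum_of_variances", n_boot=200, seed=9)
        b = sq.bootstrap_ci(rows, "sum_of_variances", n_boot=200, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.ci_high
        assert a.ci_low >= 0.0

    def test_coverage_near_nominal_for_gaussian_variance(self):
        # 1-D sum of variances == sample variance; percentile bootstrap
        # coverage of the true variance should be near 95%
        rng = np.random.default_rng(1234)
        hits = 0
        n_rep = 500
        for rep in range(n_rep):
            sample = rng.normal(0, 1, (30, 1))
            est = sq.bootstrap_ci(sample, "sum_of_variances", n_boot=200,
                                  seed=rep)
            if est.ci_low <= 1.0 <= est.ci_high:
                hits += 1
        assert 0.85 <= hits / n_rep <= 0.99

    def test_mostly_failing_metric_raises(self):
        # a 4-point hull is valid on the observed sample but degenerate in
        # most bootstrap resamples (any duplicated vertex flattens it)
        tetra = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        with pytest.raises(DegenerateGeometryError, match="failed"):
            sq.bootstrap_ci(tetra, "hull_volume", n_boot=50, seed=0)


class TestRarefaction:
    def test_target_equals_n_is_deterministic(self, rng):
        rows = rng.normal(0, 1, (8, 3))
        est = sq.rarefied_metric(rows, "sum_of_variances", target_n=8,
                                 n_iter=50, seed=0)
        assert est.value == pytest.approx(sq.sum_of_variances(rows))
        assert est.ci_low == pytest.approx(est.ci_high)

    def test_rarefied_hull_never_exceeds_full_sample(self, rng):
        rows = rng.normal(0, 1, (20, 3))
        full = sq.hull_volume(rows)
        est = sq.rarefied_metric(rows, "hull_volume", target_n=8,
                                 n_iter=100, seed=1)
        assert est.value <= full + 1e-12

    def test_mean_converges_to_exhaustive_subset_average(self, rng):
        rows = rng.normal(0, 1, (7, 2))
        target = 4
        exact = np.mean([sq.sum_of_variances(rows[list(c)])
                         for c in combinations(range(7), target)])
        est = sq.rarefied_metric(rows, "sum_of_variances", target_n=target,
                                 n_iter=20000, seed=5)
        assert est.value == pytest.approx(exact, rel=0.02)

    def test_target_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            sq.rarefied_metric(rng.normal(0, 1, (5, 3)), "sum_of_variances",
                               target_n=6)


class TestPermutationMetricTest:
    def test_identical_groups_give_p_one(self, rng):
        rows = rng.normal(0, 1, (5, 3))
        r = sq.permutation_metric_test(rows, rows.copy(), "sum_of_variances",
                                       n_iter=99, seed=0)
        assert r.observed_diff == pytest.approx(0.0)
        assert r.p_value == 1.0

    def test_exhaustive_agrees_with_independent_enumeration(self, rng):
        a = rng.normal(0, 1, (4, 2))
        b = rng.normal(0, 3, (4, 2))
        r = sq.permutation_metric_test(a, b, "sum_of_variances", exhaustive=True)
        pool = np.vstack([a, b])
        obs = sq.sum_of_variances(b) - sq.sum_of_variances(a)
        diffs = []
        for comb in combinations(range(8), 4):
            rest = [i for i in range(8) if i not in comb]
            diffs.append(sq.sum_of_variances(pool[rest])
                         - sq.sum_of_variances(pool[list(comb)]))
        expect = np.mean([abs(d) >= abs(obs) - 1e-12 for d in diffs])
        assert r.n_iterations == math.comb(8, 4)
        assert r.p_value == pytest.approx(expect)

    def test_reproducible_given_seed(self, rng):
        a, b = rng.normal(0, 1, (6, 3)), rng.normal(0, 2, (7, 3))
        r1 = sq.permutation_metric_test(a, b, "sum_of_variances", 300, seed=4)
        r2 = sq.permutation_metric_test(a, b, "sum_of_variances", 300, seed=4)
        assert r1.p_value == r2.p_value


class TestNpmanova:
    def _skbio_permanova(self, scores, labels):
        from skbio.stats.distance import DistanceMatrix, permanova
        from scipy.spatial.distance import pdist, squareform
        dm = DistanceMatrix(squareform(pdist(scores)),
                            ids=[str(i) for i in range(len(labels))])
        return permanova(dm, grouping=list(labels), permutations=99)

    def test_pseudo_f_matches_independent_permanova(self, rng):
        scores = rng.normal(0, 1, (18, 5))
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        ours = sq.npmanova(scores, labels, n_perm=99, seed=0)
        ref = self._skbio_permanova(scores, labels)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_separated_clusters_reach_minimal_exhaustive_p(self, rng):
        a = rng.normal(0, 0.01, (3, 2))
        b = rng.normal(10, 0.01, (3, 2)) + 10
        scores = np.vstack([a, b])
        labels = ["a"] * 3 + ["b"] * 3
        r = sq.npmanova(scores, labels, exhaustive=True)
        # C(6,3) = 20 assignments; observed F strictly exceeds all others
        # except itself and its mirror image (label swap)
        assert r.n_permutations == 20
        assert r.p_value == pytest.approx(2 / 20)

    def test_rotation_invariance_of_pseudo_f(self, rng):
        scores = rng.normal(0, 1, (12, 4))
        labels = ["a"] * 6 + ["b"] * 6
        q, _ = np.linalg.qr(rng.normal(0, 1, (4, 4)))
        f1 = sq.npmanova(scores, labels, n_perm=9, seed=0).pseudo_f
        f2 = sq.npmanova(scores @ q, labels, n_perm=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2)

    def test_group_of_one_rejected(self, rng):
        with pytest.raises(ValueError):
            sq.npmanova(rng.normal(0, 1, (5, 2)), ["a", "a", "a", "a", "b"])

    def test_pseudo_f_formula_direct(self):
        # two 1-D groups: SS partition computable by hand
        scores = np.array([[0.0], [1.0], [4.0], [5.0]])
        labels = np.array(["a", "a", "b", "b"])
        d2 = (scores - scores.T) ** 2
        f = _pseudo_f_from_d2(d2, labels)
        # SS_total = var decomposition: among = 16, within = 1 (0.5 + 0.5)
        grand = scores.mean()
        ss_within = sum(((scores[labels == g] -
                          scores[labels == g].mean()) ** 2).sum()
                        for g in ("a", "b"))
        ss_among = sum(2 * (scores[labels == g].mean() - grand) ** 2
                       for g in ("a", "b"))
        assert f == pytest.approx(float((ss_among / 1) / (ss_within / 2)))


class TestSnakeAugmentation:
    def _fit(self, rng, n=20):
        template = sq.load_template_jaw()
        modes = sq.deformation_modes(template)
        shapes = []
        for i in range(n):
            coef = rng.normal(0, 0.05, 3)
            pts = template + np.tensordot(coef, modes, axes=1)
            shapes.append(sq.LandmarkSet(f"s{i}", pts))
        aligned = sq.gpa_align(shapes)
        return aligned, sq.pca_embed(aligned)

    def test_single_snake_centroid_is_that_shape(self, rng):
        aligned, space = self._fit(rng)
        cen = sq.snake_centroid(aligned, space, ["s3"])
        assert np.allclose(cen.shape, aligned.coords[3])

    def test_centroid_projection_is_mean_of_member_scores(self, rng):
        aligned, space = self._fit(rng)
        ids = ["s1", "s4", "s7"]
        cen = sq.snake_centroid(aligned, space, ids)
        rows = space.scores[[1, 4, 7]]
        assert np.allclose(cen.scores, rows.mean(axis=0), atol=1e-9)

    def test_augmented_bin_hull_never_shrinks(self, rng):
        aligned, space = self._fit(rng)
        early = space.scores[:8, :3]
        groups = {"early": early}
        cen = sq.snake_centroid(aligned, space, ["s10", "s11"])
        aug = sq.snake_augment({"early": early}, cen, ["early"])
        assert aug["early"].shape[0] == early.shape[0] + 1
        v0 = sq.hull_volume(groups["early"])
        v1 = sq.hull_volume(aug["early"][:, :3])
        assert v1 >= v0 - 1e-12

    def test_empty_snake_set_rejected(self, rng):
        aligned, space = self._fit(rng, n=5)
        with pytest.raises(ValueError):
            sq.snake_centroid(aligned, space, [])
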