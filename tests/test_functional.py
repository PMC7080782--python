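import numpy as np
import pandas as pd
import pytest

from assemblage.diversity import DissimilarityMatrix, OrdinationResult, dissimilarity_matrix
from assemblage.functional import (co2_variance_series, cumulative_activity, linear_fit,
                                   mantel_test, process_function_profiles, procrustes_test)
from assemblage.io import ActivityTable, Co2Table
from conftest import make_series


class TestProcessProfiles:
    def _raw(self, rows):
        idx = pd.MultiIndex.from_tuples([("M01", 3 * i) for i in range(len(rows))])
        return pd.DataFrame(rows, index=idx, columns=["S1", "S2", "water"])

    def test_subtraction_and_clipping(self):
        table, clipped = process_function_profiles(self._raw([[0.8, 0.05, 0.1]]))
        assert np.allclose(table.values, [[0.7, 0.0]])
        assert clipped == 1

    def test_all_equal_water_gives_zero_profile(self):
        table, _ = process_function_profiles(self._raw([[0.2, 0.2, 0.2]]))
        assert np.all(table.values == 0.0)

    def test_missing_control_rejected(self):
        raw = self._raw([[0.1, 0.2, 0.0]]).drop(columns="water")
        with pytest.raises(ValueError, match="water"):
            process_function_profiles(raw)


class TestCo2Variance:
    def test_identical_values_zero_variance(self):
        co2 = Co2Table(index=[("M01", 3), ("M02", 3)], percent_co2=[2.0, 2.0])
        assert co2_variance_series(co2) == {3: 0.0}

    def test_sample_variance_denominator(self):
        co2 = Co2Table(index=[("M01", 3), ("M02", 3)], percent_co2=[1.0, 3.0])
        assert co2_variance_series(co2)[3] == pytest.approx(2.0)

    def test_single_value_day_skipped_with_warning(self):
        co2 = Co2Table(index=[("M01", 0), ("M01", 3), ("M02", 3)],
                       percent_co2=[5.0, 1.0, 3.0])
        with pytest.warns(UserWarning):
            out = co2_variance_series(co2)
        assert list(out) == [3]

    def test_day0_variance_dominates_on_synthetic(self, default_synthetic):
        *_, co2, _, _ = default_synthetic
        var = co2_variance_series(co2)
        assert var[0] > max(v for d, v in var.items() if d > 0)


class TestMantel:
    def _d(self, X, metric="euclidean"):
        return dissimilarity_matrix(X, metric=metric)

    def test_self_comparison_attains_minimum_p(self):
        d = self._d(np.random.default_rng(0).random((10, 3)))
        res = mantel_test(d, d, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_monotone_transform_preserves_significance(self):
        rng = np.random.default_rng(1)
        d1 = self._d(rng.random((12, 3)))
        d2 = DissimilarityMatrix(d1.sample_ids, np.sqrt(d1.values))
        res = mantel_test(d1, d2, n_perm=199, seed=1)
        assert res.r > 0.9
        assert res.p_value == pytest.approx(1 / 200)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        d1 = self._d(rng.random((9, 4)))
        d2 = self._d(rng.random((9, 4)))
        perm = rng.permutation(9)
        relabel = lambda d: DissimilarityMatrix(
            [d.sample_ids[i] for i in perm], d.values[np.ix_(perm, perm)])
        a = mantel_test(d1, d2, n_perm=99, seed=3)
        b = mantel_test(relabel(d1), relabel(d2), n_perm=99, seed=3)
        assert a.r == pytest.approx(b.r)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        X = rng.random((11, 5))
        d1, d2 = self._d(X), self._d(X + 0.4 * rng.random((11, 5)))
        ours = mantel_test(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1.values), skbio.DistanceMatrix(d2.values),
            permutations=0)
        assert ours.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_seeded_reproducibility_and_add_one_rule(self):
        rng = np.random.default_rng(4)
        d1, d2 = self._d(rng.random((8, 3))), self._d(rng.random((8, 3)))
        a = mantel_test(d1, d2, n_perm=299, seed=9)
        b = mantel_test(d1, d2, n_perm=299, seed=9)
        assert a.p_value == b.p_value > 0
        assert a.p_value >= 1 / 300

    def test_mismatched_samples_rejected(self):
        d1 = DissimilarityMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        d2 = DissimilarityMatrix(["a", "b", "c", "e"], np.zeros((4, 4)))
        with pytest.raises(ValueError):
            mantel_test(d1, d2)


class TestProcrustes:
    def _rot(self, theta):
        return np.array([[np.cos(theta), -np.sin(theta)],
                         [np.sin(theta), np.cos(theta)]])

    def test_similarity_invariance(self):
        rng = np.random.default_rng(5)
        A = rng.random((12, 2))
        B = 3.7 * A @ self._rot(1.1) + np.array([5.0, -2.0])
        ids = [str(i) for i in range(12)]
        res = procrustes_test(OrdinationResult(ids, A, "pcoa"),
                              OrdinationResult(ids, B, "pcoa"), n_perm=99, seed=0)
        assert res.correlation == pytest.approx(1.0, abs=1e-9)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-9)

    def test_reflection_invariance(self):
        rng = np.random.default_rng(6)
        A = rng.random((10, 2))
        B = A @ np.diag([1.0, -1.0])
        ids = [str(i) for i in range(10)]
        res = procrustes_test(OrdinationResult(ids, A, "pcoa"),
                              OrdinationResult(ids, B, "pcoa"), n_perm=49, seed=0)
        assert res.correlation == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(7)
        A, B = rng.random((10, 2)), rng.random((10, 2))
        ids = [str(i) for i in range(10)]
        res = procrustes_test(OrdinationResult(ids, A, "pcoa"),
                              OrdinationResult(ids, B, "pcoa"), n_perm=49, seed=0)
        _, _, disparity = scipy_procrustes(A, B)
        assert res.m12_squared == pytest.approx(disparity, abs=1e-10)
        assert res.correlation == pytest.approx(np.sqrt(1 - disparity), abs=1e-10)

    def test_two_point_degeneracy_flagged(self):
        ids = ["a", "b"]
        A = np.array([[0.0, 0.0], [1.0, 1.0]])
        B = np.array([[3.0, 1.0], [0.0, 2.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            res = procrustes_test(OrdinationResult(ids, A, "pcoa"),
                                  OrdinationResult(ids, B, "pcoa"), n_perm=9, seed=0)
        assert res.correlation == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        ids = [str(i) for i in range(5)]
        with pytest.raises(ValueError):
            procrustes_test(OrdinationResult(ids, np.random.rand(5, 2), "pcoa"),
                            OrdinationResult(ids, np.random.rand(5, 3), "pcoa"))


class TestCumulativeActivity:
    def _activity(self, mapping):
        df = pd.DataFrame(mapping, index=["endochitinase", "protease", "lipase"]).T
        return ActivityTable(asv_ids=list(df.index), activities=df)

    def test_single_asv_full_abundance(self):
        s = make_series({"a": range(22)})
        act = self._activity({"a": [5.0, 0.0, 0.0]})
        out = cumulative_activity(act, s)
        assert all(v == pytest.approx(5.0) for v in out.values())

    def test_unmeasured_asvs_contribute_zero(self):
        s = make_series({"a": range(22), "mystery": range(22)})
        act = self._activity({"a": [4.0, 0, 0]})
        out = cumulative_activity(act, s)
        assert all(v == pytest.approx(2.0) for v in out.values())

    def test_linear_in_activity(self):
        s = make_series({"a": range(22), "b": range(22)})
        one = cumulative_activity(self._activity({"a": [1, 0, 0], "b": [3, 0, 0]}), s)
        two = cumulative_activity(self._activity({"a": [2, 0, 0], "b": [6, 0, 0]}), s)
        for d in one:
            assert two[d] == pytest.approx(2 * one[d])


class TestLinearFit:
    def test_exact_line_with_intercept(self):
        x = np.arange(3, 10, dtype=float)
        (slope, intercept), r2, p = linear_fit(x, 2 * x + 1)
        assert (slope, intercept) == (pytest.approx(2.0), pytest.approx(1.0))
        assert r2 == pytest.approx(1.0)

    def test_no_intercept_matches_closed_form(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            (beta,), r2, p = linear_fit(x, y, with_intercept=False)
            assert beta == pytest.approx(float(x @ y / (x @ x)), abs=1e-12)
            assert 0 <= p <= 1

    def test_orthogonal_no_intercept_r2_near_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        (beta,), r2, _ = linear_fit(x, y, with_intercept=False)
        assert beta == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_projected_activity_tracks_community_on_synthetic(self, default_synthetic):
        exp, functions, co2, activities, truth = default_synthetic
        s = exp.series[0]
        projected = cumulative_activity(activities, s)
        # oracle: recompute from ground-truth activities and composition
        truth_act = truth.activities["endochitinase"]
        expected = {}
        for i, day in enumerate(s.days):
            expected[int(day)] = float(sum(
                s.rel_abundance[i, j] * truth_act.get(a, 0.0)
                for j, a in enumerate(s.asv_ids)))
        for d in projected:
            assert projected[d] == pytest.approx(expected[d], abs=1e-9)
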