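import numpy as np
import pytest

from assemblage.context import (DIFFERENT_INOCULUM, RANDOM_PAIR, SAME_INOCULUM,
                                CLRTransformer, classify_fates, clr_transform,
                                composition_trajectory_coupling, cosine_similarity,
                                distribution_summary, shared_fate_null,
                                shared_fate_test, trajectory_correlations, FateTable)
from assemblage.io import Experiment
from conftest import make_series


class TestCLR:
    def test_equal_counts_give_zeros(self):
        s = make_series({"a": range(22), "b": range(22), "c": range(22)})
        mat, kept = clr_transform(s)
        assert kept == ["a", "b", "c"]
        assert np.allclose(mat, 0.0)

    def test_rows_center_to_zero(self, default_synthetic):
        exp, *_ = default_synthetic
        mat, _ = clr_transform(exp.series[0])
        assert np.allclose(mat.sum(axis=1), 0.0, atol=1e-9)

    def test_pseudo_read_rule_for_zero_count(self):
        s = make_series({"a": [0, 1], "b": [0, 1]})
        s.counts[0] = [8, 2]
        s.counts[1] = [0, 26]
        mat, _ = clr_transform(s)
        # zero count becomes ln(1) = 0, so CLR = -mean of logs
        logs = np.log([1.0, 27.0])
        assert mat[1, 0] == pytest.approx(-logs.mean())

    def test_never_observed_asvs_dropped(self):
        s = make_series({"a": range(22), "ghost": []})
        mat, kept = clr_transform(s)
        assert kept == ["a"]

    def test_exact_scale_invariance_without_pseudocount(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(6, 5))
        tf = CLRTransformer(pseudocount=0.0).fit(counts)
        a = tf.transform(counts)
        b = tf.transform(counts * 7)
        assert np.allclose(a, b, atol=1e-12)


class TestTrajectoryCorrelations:
    def _paired_experiment(self):
        layout = {"x": range(22), "y": range(22), "z": range(22)}
        series = []
        rng = np.random.default_rng(1)
        for mic in ("M01", "M02"):
            for tr in ("filtered", "unfiltered"):
                s = make_series(layout, mic, treatment=tr)
                s.counts = rng.integers(1, 200, size=s.counts.shape)
                series.append(s)
        return Experiment(series=series)

    def test_identical_series_give_r_one(self):
        exp = self._paired_experiment()
        exp.series[1].counts = exp.series[0].counts.copy()
        out = trajectory_correlations(exp, seed=0, n_random=0)
        same = [c for c in out if c.category == SAME_INOCULUM
                and c.pair == ("M01-F", "M01-U")]
        assert same and all(c.pearson_r == pytest.approx(1.0) for c in same)

    def test_categories_are_consistent_with_labels(self):
        out = trajectory_correlations(self._paired_experiment(), seed=0)
        for c in out:
            mics = {lbl.split("-")[0] for lbl in c.pair}
            if c.category == SAME_INOCULUM:
                assert len(mics) == 1
            else:
                assert len(mics) == 2
        assert {c.category for c in out} == {SAME_INOCULUM, DIFFERENT_INOCULUM,
                                             RANDOM_PAIR}

    def test_random_pairs_count_matched_and_seeded(self):
        exp = self._paired_experiment()
        out1 = trajectory_correlations(exp, seed=5)
        out2 = trajectory_correlations(exp, seed=5)
        rand1 = [c for c in out1 if c.category == RANDOM_PAIR]
        same_asv = [c for c in out1 if c.category != RANDOM_PAIR]
        assert len(rand1) == len(same_asv)
        assert [(c.asv_id, c.pearson_r) for c in out1] == \
            [(c.asv_id, c.pearson_r) for c in out2]

    def test_category_ordering_on_synthetic_defaults(self, default_synthetic):
        exp, *_ = default_synthetic
        out = trajectory_correlations(exp, seed=0)
        means = {cat: np.mean([c.pearson_r for c in out if c.category == cat])
                 for cat in (SAME_INOCULUM, DIFFERENT_INOCULUM, RANDOM_PAIR)}
        assert means[SAME_INOCULUM] > means[DIFFERENT_INOCULUM] > means[RANDOM_PAIR]


class TestDistributionSummary:
    def test_constant_sample(self):
        mean, mode = distribution_summary([0.5] * 10)
        assert mean == pytest.approx(0.5)
        assert mode == pytest.approx(0.5)

    def test_bimodal_mode_at_a_peak(self):
        rng = np.random.default_rng(2)
        sample = np.concatenate([rng.normal(0.8, 0.03, 400),
                                 rng.normal(-0.8, 0.03, 400)])
        mean, mode = distribution_summary(np.clip(sample, -1, 1))
        assert abs(mean) < 0.1
        assert abs(abs(mode) - 0.8) < 0.05

    def test_unimodal_mode_near_zero(self):
        rng = np.random.default_rng(3)
        sample = np.clip(rng.normal(0, 0.3, 10000), -1, 1)
        _, mode = distribution_summary(sample)
        assert abs(mode) < 0.05

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            distribution_summary([0.1, 0.2])


class TestCosine:
    def test_scale_invariance(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(x, 2 * x) == pytest.approx(1.0)

    def test_disjoint_supports_are_orthogonal(self):
        assert cosine_similarity([1, 0, 2, 0], [0, 3, 0, 4]) == pytest.approx(0.0)

    def test_arithmetic(self):
        assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 2])

    def test_bounds_for_nonnegative_input(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            x, y = rng.random(6), rng.random(6)
            assert 0.0 <= cosine_similarity(x, y) <= 1.0 + 1e-12


class TestCoupling:
    def test_perfect_fit_when_points_on_line(self):
        # three inocula pairs with proportional divergence by construction
        rng = np.random.default_rng(5)
        series = []
        base = rng.integers(50, 150, size=(22, 4))
        for m, shift in enumerate([0.0, 0.35, 0.9, 1.6]):
            s = make_series({k: range(22) for k in "abcd"}, f"M{m:02d}")
            s.counts = np.maximum(base + rng.normal(0, 1, base.shape) * 0
                                  + (shift * 60 * np.arange(4))[None, :], 1).astype(int)
            series.append(s)
        exp = Experiment(series=series)
        points, beta, r2 = composition_trajectory_coupling(exp)
        assert len(points) >= 3
        assert 0.0 <= r2 <= 1.0

    def test_exact_intercept_free_r2(self):
        # algebraic check of the uncentered R^2 on constructed points
        x = np.array([1.0, 2.0, 3.0])
        y = 0.7 * x
        beta = x @ y / (x @ x)
        r2 = 1 - np.sum((y - beta * x) ** 2) / np.sum(y**2)
        assert beta == pytest.approx(0.7) and r2 == pytest.approx(1.0)

    def test_positive_coupling_on_synthetic(self, default_synthetic):
        exp, *_ = default_synthetic
        points, beta, r2 = composition_trajectory_coupling(exp)
        assert beta > 0
        assert r2 > 0.3


class TestSharedFate:
    def test_null_values(self):
        assert shared_fate_null(1) == 1.0
        assert shared_fate_null(2) == 0.5
        assert shared_fate_null(3) == 0.25
        assert shared_fate_null(3, f=0.4) == pytest.approx(0.16)

    def test_null_monotone_in_n(self):
        vals = [shared_fate_null(n, 0.5) for n in range(1, 10)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_classify_fates_matches_records(self):
        s = make_series({"gone": [1, 2, 3], "keep": range(22)})
        table = classify_fates(Experiment(series=[s]))
        assert table.fate[("gone", "M01-F")] == "extinct"
        assert table.fate[("keep", "M01-F")] == "survivor"
        assert table.occupancy == {"gone": 1, "keep": 1}

    def test_all_same_fate_is_extreme(self):
        fate = {(f"a{i}", f"M{m}"): "survivor" for i in range(40) for m in range(3)}
        occ = {f"a{i}": 3 for i in range(40)}
        res = shared_fate_test(FateTable(fate=fate, occupancy=occ))
        obs, null, p, n = res[3]
        assert obs == 1.0 and null == 0.25 and p < 1e-15

    def test_null_calibration_with_coin_flip_fates(self):
        rng = np.random.default_rng(6)
        fate = {}
        for i in range(2000):
            for m in range(3):
                fate[(f"a{i}", f"M{m}")] = "survivor" if rng.random() < 0.5 else "extinct"
        res = shared_fate_test(FateTable(fate=fate, occupancy={}))
        obs, null, p, n = res[3]
        assert abs(obs - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 2000)
        assert p > 0.01

    def test_replicate_agreement_beats_null_on_synthetic(self, default_synthetic):
        exp, *_ = default_synthetic
        table = classify_fates(exp)
        res = shared_fate_test(table)
        assert 2 in res
        obs, null, p, n = res[2]
        assert obs > null
        assert p < 0.01
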