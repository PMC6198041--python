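"""Imaging pipeline: baselines, AUC, normalization, paired statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mbx.imaging import (
    Epoch,
    FluorescenceTrace,
    analyze_cohort,
    compute_dff,
    normalize_to_novel,
    odor_response_auc,
    optogenetic_response,
    paired_group_test,
)
from mbx.synth import ImagingGenSpec, gen_imaging_cohort

RATE = 5.92


def make_trace(samples, epochs=()):
    return FluorescenceTrace(np.asarray(samples, float), RATE, list(epochs))


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        trace = make_trace(np.full(100, 50.0), [Epoch("CS+", 10.0, 5.0)])
        assert np.allclose(compute_dff(trace, "pre_odor_2s", "CS+"), 0.0)
        assert np.allclose(compute_dff(trace, "first_9s"), 0.0)

    def test_plateau_closed_form(self):
        f = np.full(200, 100.0)
        f[80:] = 200.0
        trace = make_trace(f, [Epoch("CS+", 80 / RATE, 5.0)])
        dff = compute_dff(trace, "pre_odor_2s", "CS+")
        assert dff[100] == pytest.approx(1.0)

    def test_matches_elementwise_formula(self, rng):
        f = 100 + rng.normal(0, 5, 300)
        trace = make_trace(f, [Epoch("CS+", 20.0, 5.0)])
        dff = compute_dff(trace, "pre_odor_2s", "CS+")
        stop = trace.sample_index(20.0)
        start = trace.sample_index(18.0)
        f0 = f[start:stop].mean()
        assert np.allclose(dff, (f - f0) / f0)
        dff9 = compute_dff(trace, "first_9s")
        f0_9 = f[: trace.sample_index(9.0)].mean()
        assert np.allclose(dff9, (f - f0_9) / f0_9)

    def test_non_positive_baseline_raises(self):
        trace = make_trace(np.zeros(100), [Epoch("CS+", 10.0, 5.0)])
        with pytest.raises(ValueError, match="non-positive baseline"):
            compute_dff(trace, "first_9s")


class TestAuc:
    def test_zero_series(self):
        assert odor_response_auc(np.zeros(100), RATE, 5.0) == 0.0

    def test_unit_boxcar_rectangle_area(self):
        # boxcar covering the whole window at 1 kHz (window edges on grid)
        y = np.zeros(20_000)
        y[5000:10_001] = 1.0
        assert odor_response_auc(y, 1000.0, 5.0, 5.0) == pytest.approx(5.0)

    def test_window_outside_record_raises(self):
        with pytest.raises(ValueError, match="window"):
            odor_response_auc(np.zeros(30), RATE, 4.0, 5.0)

    def test_smooth_response_close_to_fine_grid_integral(self):
        t_coarse = np.arange(0, 30, 1 / RATE)
        t_fine = np.arange(0, 30, 1e-3)
        resp = lambda t: np.exp(-((t - 12.0) ** 2) / 4.0)
        auc = odor_response_auc(resp(t_coarse), RATE, 10.0, 5.0)
        i0, i1 = int(10.0 / 1e-3), int(15.0 / 1e-3)
        fine = np.trapezoid(resp(t_fine)[i0:i1 + 1], dx=1e-3)
        assert auc == pytest.approx(fine, rel=0.01)

    @given(st.floats(-2, 2), st.floats(-2, 2))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=200), rng.normal(size=200)
        lhs = odor_response_auc(a * x + b * y, RATE, 10.0, 5.0)
        rhs = (a * odor_response_auc(x, RATE, 10.0, 5.0)
               + b * odor_response_auc(y, RATE, 10.0, 5.0))
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestNormalization:
    def test_ratio_arithmetic(self):
        assert normalize_to_novel(2.4, 1.2) == pytest.approx(2.0)
        assert normalize_to_novel(1.2, 1.2) == pytest.approx(1.0)

    def test_near_zero_novel_flagged(self):
        with pytest.warns(UserWarning, match="excluded"):
            assert np.isnan(normalize_to_novel(1.0, 1e-12, eps=1e-6))

    def test_gain_invariance(self):
        """Scaling a fly's raw F by any c > 0 leaves normalized AUCs unchanged."""
        traces, _ = gen_imaging_cohort(ImagingGenSpec(n_flies=1, seed=4))
        from mbx.imaging import odor_responses
        base = odor_responses(traces[0])
        for c in (0.25, 7.0):
            scaled = FluorescenceTrace(traces[0].samples * c, traces[0].sampling_rate,
                                       traces[0].epochs, traces[0].fly_id, traces[0].roi)
            got = odor_responses(scaled)
            for odor in ("CS+", "CS-"):
                assert got[odor].normalized_auc == pytest.approx(
                    base[odor].normalized_auc, rel=1e-9)


class TestPairedGroupTest:
    def test_identical_vectors_degenerate(self):
        x = np.arange(10.0)
        res = paired_group_test(x, x)
        assert res.test_used == "degenerate" and res.p == 1.0

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match="5"):
            paired_group_test([1, 2], [3, 4])

    def test_gate_routes_nonnormal_to_wilcoxon(self, rng):
        base = rng.normal(0, 1, 40)
        heavy = base + rng.standard_cauchy(40) * 5
        res = paired_group_test(heavy, base)
        assert res.test_used == "Wilcoxon signed-rank"

    def test_power_on_planted_shift(self):
        """Planted 1-sd shift, n=20: rejection rate >= 80% at alpha 0.05."""
        rejections = 0
        n_sim = 500
        rng = np.random.default_rng(1)
        for _ in range(n_sim):
            b = rng.normal(0, 1, 20)
            a = b + rng.normal(1.0, 1.0, 20)
            rejections += paired_group_test(a, b).p < 0.05
        assert rejections / n_sim >= 0.80

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            rejections += paired_group_test(a, b).p < 0.05
        assert 0.035 <= rejections / n_sim <= 0.065

    def test_boxplot_summary_consistent(self, rng):
        a, b = rng.normal(1, 0.2, 12), rng.normal(1, 0.2, 12)
        res = paired_group_test(a, b)
        assert res.boxplot["CS+"]["median"] == pytest.approx(np.median(a))
        assert res.boxplot["CS+"]["min"] == pytest.approx(a.min())
        assert res.boxplot["CS-"]["q1"] == pytest.approx(np.percentile(b, 25))


class TestOptogenetic:
    def test_flat_traces_null(self):
        traces = [np.zeros(120) for _ in range(6)]
        res = optogenetic_response(traces, RATE, stim_onset_s=10.0)
        assert res["p"] == 1.0
        assert np.allclose(res["pre_means"], res["post_means"])

    def test_planted_step_detected(self, rng):
        traces = []
        for _ in range(10):
            y = rng.normal(0, 0.05, 120)
            y[int(10 * RATE):] += 0.5
            traces.append(y)
        res = optogenetic_response(traces, RATE, stim_onset_s=10.0)
        assert res["p"] < 0.05
        assert res["post_means"].mean() > res["pre_means"].mean()

    def test_onset_too_early_raises(self):
        with pytest.raises(ValueError, match="1 s"):
            optogenetic_response([np.zeros(60)], RATE, stim_onset_s=0.5)


class TestCohortRecovery:
    def test_depression_direction_recovered(self):
        res = analyze_cohort(gen_imaging_cohort(
            ImagingGenSpec(csplus_multiplier=0.7, seed=21))[0])
        diffs = res.pairs[:, 0] - res.pairs[:, 1]
        assert np.median(diffs) < 0 and res.p < 0.05

    def test_mean_ratio_recovers_planted_depression(self):
        """30% planted CS+ depression: mean CS+/CS- ratio of the baseline-
        subtracted responses lands near 0.7."""
        ratios = []
        for seed in range(20):
            traces, _ = gen_imaging_cohort(ImagingGenSpec(
                csplus_multiplier=0.7, seed=seed))
            from mbx.imaging import odor_responses
            for trace in traces:
                resp = odor_responses(trace, integrand="dff")
                ratios.append(resp["CS+"].normalized_auc / resp["CS-"].normalized_auc)
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.05)

    def test_null_median_shrinks_with_n(self):
        """With no planted effect, |median(CS+ - CS-)| shrinks roughly as
        1/sqrt(n) on average across seeds."""
        med = {n: [] for n in (5, 45)}
        for n in med:
            for seed in range(40):
                traces, _ = gen_imaging_cohort(ImagingGenSpec(
                    n_flies=n, csplus_multiplier=1.0, seed=seed))
                res = analyze_cohort(traces)
                med[n].append(abs(np.median(res.pairs[:, 0] - res.pairs[:, 1])))
        assert np.mean(med[45]) < np.mean(med[5])
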