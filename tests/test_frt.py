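"""Respiratory-frequency threshold detection: scan, segments, intersections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frthresh.exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    NoIntersectionError,
)
from frthresh.frt import (
    RespiratoryThresholdModel,
    detect_frt,
    map_threshold,
    running_baseline,
    scan_provisional,
)
from frthresh.regression import RegressionLine, fit_line, intersect

from conftest import make_series


class TestRunningBaseline:
    @pytest.mark.parametrize("values, mean, sd", [
        ([12.7, 16.5, 14.7, 18.9, 17.5], 16.1, 2.42),
        ([12.7, 16.5, 14.7, 18.9, 17.5, 21.5, 19.3, 22.1], 17.9, 3.23),
    ])
    def test_worked_example_rows_at_display_precision(self, values, mean, sd):
        m, s = running_baseline(values)
        assert round(m, 1) == mean
        assert round(s, 2) == sd

    def test_constant_series(self):
        m, s = running_baseline([5, 5, 5, 5])
        assert m == 5 and s == 0

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            running_baseline([5])

    def test_sample_denominator(self):
        # n-1 denominator distinguishes 2.42 from the population value 2.17
        _, s = running_baseline([12.7, 16.5, 14.7, 18.9, 17.5])
        assert s == pytest.approx(np.std([12.7, 16.5, 14.7, 18.9, 17.5], ddof=1))


class TestProvisionalScan:
    def test_worked_example_triggers_at_100_and_160_w(self, example_series):
        scan, pt1, pt2 = scan_provisional(example_series)
        assert example_series.stages[pt1].po == 100
        assert example_series.stages[pt2].po == 160

    def test_60w_stage_excess_exceeds_gate_but_is_ineligible(self, example_series):
        # the strict PO > 60 W rule: the 60 W row satisfies excess > gate
        scan, pt1, _ = scan_provisional(example_series)
        row = scan[scan.po_watts == 60].iloc[0]
        assert row.excess > row.gate
        assert not row.eligible and not row.triggered
        assert example_series.stages[pt1].po == 100

    def test_truncated_series_keeps_pt1_loses_pt2(self, example_series):
        truncated = make_series(
            *(example_series.column(c)[:8] for c in ("po", "hr", "fr")))
        _, pt1, pt2 = scan_provisional(truncated)
        assert truncated.stages[pt1].po == 100
        assert pt2 is None

    def test_noise_free_linear_fr_never_triggers(self):
        po = np.arange(0, 261, 20.0)
        hr = 90 + 0.4 * po
        for slope in (0.2, 1.0, 3.0):  # representative f_R growth rates
            fr = 12 + slope * np.arange(po.size)
            _, pt1, pt2 = scan_provisional(make_series(po, hr, fr))
            assert pt1 is None and pt2 is None

    def test_trailing_stages_do_not_move_triggers(self, example_series):
        scan_full, pt1_full, pt2_full = scan_provisional(example_series)
        truncated = make_series(
            *(example_series.column(c)[:10] for c in ("po", "hr", "fr")))
        _, pt1, pt2 = scan_provisional(truncated)
        assert (pt1, pt2) == (pt1_full, pt2_full)

    @settings(max_examples=30, deadline=None)
    @given(shift=st.floats(-5, 50), scale=st.floats(0.2, 5.0))
    def test_trigger_decisions_invariant_to_affine_fr_rescaling(
            self, shift, scale):
        from frthresh.datasets import example_participant

        example_series = example_participant()
        fr = scale * example_series.fr + shift
        if np.any(fr <= 0):
            return
        series = make_series(example_series.po, example_series.hr, fr)
        base = scan_provisional(example_series)[0]
        scan = scan_provisional(series)[0]
        assert (scan.triggered == base.triggered).all()
        # mean shifts/scales exactly; SD scales only
        np.testing.assert_allclose(scan.avg_prev[1:],
                                   scale * base.avg_prev[1:] + shift, rtol=1e-9)
        np.testing.assert_allclose(scan.sd_prev[2:],
                                   scale * base.sd_prev[2:], rtol=1e-9)


class TestFitLine:
    def test_worked_example_first_segment_coefficients(self, example_series):
        line = fit_line(example_series.hr[:6], example_series.fr[:6])
        assert round(line.slope, 4) == 0.1399
        assert round(line.intercept, 4) == 1.9233

    def test_two_points_exact(self):
        line = fit_line([1.0, 3.0], [2.0, 8.0])
        assert line.slope == pytest.approx(3.0)
        assert line.sse == pytest.approx(0.0, abs=1e-20)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=20))
    def test_matches_normal_equations(self, points):
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        if np.ptp(x) < 1e-6:
            return
        # closed-form normal equations, computed independently
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        line = fit_line(x, y)
        assert line.slope == pytest.approx(beta[0], rel=1e-6, abs=1e-8)
        assert line.intercept == pytest.approx(beta[1], rel=1e-6, abs=1e-8)

    def test_identical_predictors_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestIntersect:
    def test_worked_example_intersections(self, example_series):
        hr, fr = example_series.hr, example_series.fr
        rl1 = fit_line(hr[:6], fr[:6])
        rl2 = fit_line(hr[5:9], fr[5:9])
        rl3 = fit_line(hr[8:], fr[8:])
        h1, f1 = intersect(rl1, rl2)
        h2, f2 = intersect(rl2, rl3)
        assert round(f1, 1) == 22.3
        assert round(f2, 1) == 29.3
        # full-precision HR coordinates of the fitted-line crossings
        assert h1 == pytest.approx(145.4, abs=0.05)
        assert h2 == pytest.approx(166.5, abs=0.05)

    def test_parallel_lines_rejected(self):
        a = RegressionLine(slope=1.0, intercept=0.0, n=5, sse=0.0)
        b = RegressionLine(slope=1.0, intercept=3.0, n=5, sse=0.0)
        with pytest.raises(NoIntersectionError):
            intersect(a, b)


class TestDetect:
    def test_worked_example_full_pipeline(self, example_series):
        res = detect_frt(example_series)
        assert res.frt1.determined and res.frt2.determined
        assert round(res.lines["RL2"].slope, 4) == 0.3333
        assert round(res.lines["RL2"].intercept, 3) == -26.179
        assert round(res.lines["RL3"].slope, 4) == 2.3453
        assert round(res.lines["RL3"].intercept, 2) == -361.17
        assert round(res.frt1.fr, 1) == 22.3
        assert round(res.frt2.fr, 1) == 29.3
        assert res.frt1.hr <= res.frt2.hr
        assert res.frt1.vo2 is None  # no gas channels to map onto

    def test_no_trigger_gives_reason_codes(self):
        po = np.arange(0, 141, 20.0)
        hr = 90 + 0.4 * po
        fr = 12 + 0.3 * np.arange(po.size)  # linear: never triggers
        res = detect_frt(make_series(po, hr, fr))
        assert not res.frt1.determined and not res.frt2.determined
        assert res.frt1.reason == "no-provisional-T1"

    def test_short_series_undetermined_not_raised(self):
        po = [0, 20, 40, 60, 80]
        res = detect_frt(make_series(po, [90, 95, 100, 108, 118],
                                     [12, 13, 12.5, 14, 13.5]))
        assert res.frt1.reason == "insufficient-stages"

    def test_noise_free_breakpoints_recovered_within_one_stage(self):
        from frthresh.synthetic import NoiseSD, SubjectParams, generate_series

        params = SubjectParams(noise_sd=NoiseSD(0, 0, 0, 0, 0))
        series, truth = generate_series(params)
        res = detect_frt(series)
        hr_per_stage = params.hr_slope * params.increment_w
        assert res.frt1.determined and res.frt2.determined
        assert abs(res.frt1.hr - truth.frt1_hr) <= hr_per_stage
        assert abs(res.frt2.hr - truth.frt2_hr) <= hr_per_stage


class TestMapThreshold:
    def test_exact_linear_construction(self, linear_gas_series):
        vo2_t, po_t = map_threshold(linear_gas_series, hr_t=140.0)
        assert vo2_t == pytest.approx(2.1, abs=1e-9)
        assert po_t == pytest.approx(160.0, abs=1e-6)

    def test_matches_composed_closed_form_fits(self):
        rng = np.random.default_rng(11)
        po = np.arange(0, 201, 20.0)
        hr = 70 + 0.45 * po + rng.normal(0, 2, po.size)
        vo2 = 0.4 + 0.011 * po + rng.normal(0, 0.05, po.size)
        series = make_series(po, hr, 12 + 0.1 * np.arange(po.size), vo2=vo2)
        vo2_t, po_t = map_threshold(series, hr_t=120.0)
        hr_fit = fit_line(hr, vo2)
        po_fit = fit_line(po, vo2)
        assert vo2_t == pytest.approx(hr_fit.predict(120.0))
        assert po_t == pytest.approx((vo2_t - po_fit.intercept) / po_fit.slope)

    def test_noisy_recovery_close_to_truth(self):
        # po_t should land near 160 W despite vo2 noise, across seeds
        errors = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            po = np.arange(0, 261, 20.0)
            hr = 60 + 0.5 * po
            vo2 = 0.5 + 0.01 * po + rng.normal(0, 0.05, po.size)
            series = make_series(po, hr, 12 + 0.1 * np.arange(po.size), vo2=vo2)
            _, po_t = map_threshold(series, hr_t=140.0)
            errors.append(abs(po_t - 160.0))
        assert np.median(errors) < 10.0  # ~2 SEE of the po regression

    def test_missing_vo2_channel_rejected(self, example_series):
        with pytest.raises(InsufficientDataError):
            map_threshold(example_series, hr_t=140.0)
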