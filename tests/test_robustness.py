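"""Shift protocols, error metrics, CKD staging and sample windows."""

import numpy as np
import pytest
from scipy.stats import norm

from lssrobust.robustness import (CKD_STAGE_BINS, DEFAULT_SCHEDULE,
                                  DEFAULT_TRUNCATION_WINDOWS_H, ErrorMetrics,
                                  ProtocolError, RandomShiftProtocol,
                                  SamplingSchedule, SingleShiftProtocol,
                                  apply_random_shift, apply_single_shift,
                                  ckd_stage, evaluate_protocol,
                                  evaluate_schedule, sample_observations,
                                  window_from_rsd, window_from_single_shifts)


class TestSingleShift:
    def test_zero_shift_keeps_schedule(self):
        out = apply_single_shift(DEFAULT_SCHEDULE, 2, 0.0)
        assert out.times_h == DEFAULT_SCHEDULE.times_h

    def test_last_point_delayed_to_24h(self):
        out = apply_single_shift(DEFAULT_SCHEDULE, 3, 1140.0)
        assert out.times_h[3] == pytest.approx(24.0)

    def test_first_point_shifted_to_4min(self):
        out = apply_single_shift(DEFAULT_SCHEDULE, 0, -6.0)
        assert out.times_h[0] == pytest.approx(4 / 60)

    def test_shift_to_nonpositive_time_rejected(self):
        with pytest.raises(ProtocolError):
            apply_single_shift(DEFAULT_SCHEDULE, 0, -10.0)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ProtocolError):
            apply_single_shift(DEFAULT_SCHEDULE, 0, 30.0)  # 10min -> 40min

    def test_default_grids_cover_all_points(self):
        protos = SingleShiftProtocol.defaults()
        assert [p.point_index for p in protos] == [0, 1, 2, 3]
        assert 1140 in protos[3].deltas_min


class TestRandomShift:
    def test_draws_stay_in_windows(self):
        proto = RandomShiftProtocol(rsd=0.25)
        times = apply_random_shift(DEFAULT_SCHEDULE, proto, 2000, seed=0)
        for k, (lo, hi) in enumerate(DEFAULT_TRUNCATION_WINDOWS_H):
            assert times[:, k].min() >= lo
            assert times[:, k].max() <= hi
        assert np.all(np.diff(times, axis=1) > 0)

    def test_small_rsd_concentrates_at_nominal(self):
        proto = RandomShiftProtocol(rsd=1e-6)
        times = apply_random_shift(DEFAULT_SCHEDULE, proto, 100, seed=0)
        np.testing.assert_allclose(times,
                                   np.tile(DEFAULT_SCHEDULE.as_array(),
                                           (100, 1)), rtol=1e-4)

    def test_moment_oracle_at_low_rsd(self):
        """At 5% RSD truncation is negligible and the empirical SD of each
        point's times approaches rsd * t_k."""
        proto = RandomShiftProtocol(rsd=0.05)
        times = apply_random_shift(DEFAULT_SCHEDULE, proto, 10_000, seed=1)
        for k, t_k in enumerate(DEFAULT_SCHEDULE.as_array()):
            sd = times[:, k].std(ddof=1)
            assert sd == pytest.approx(0.05 * t_k, rel=0.05)

    def test_reproducible_and_overlap_free_windows_enforced(self):
        proto = RandomShiftProtocol(rsd=0.2)
        a = apply_random_shift(DEFAULT_SCHEDULE, proto, 50, seed=7)
        b = apply_random_shift(DEFAULT_SCHEDULE, proto, 50, seed=7)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ProtocolError):
            RandomShiftProtocol(rsd=0.1,
                                windows_h=((0.1, 0.5), (0.4, 1.0),
                                           (1.0, 3.0), (3.0, 8.0)))


class TestSampleObservations:
    def test_nominal_times_match_stored_curve(self, small_cohort):
        subject = small_cohort[0]
        # 10 min, 30 min, 2 h and 5 h all lie on the 1-min grid
        times = np.array([10 / 60, 30 / 60, 2.0, 5.0])
        obs = sample_observations(subject, times)
        idx = np.searchsorted(subject.curve.times, times)
        np.testing.assert_allclose(obs.concentrations,
                                   subject.curve.concentrations[idx],
                                   rtol=1e-9)

    def test_at_dose_time_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            sample_observations(small_cohort[0], np.array([0.0, 1.0]))

    def test_off_grid_time_close_to_interpolated_curve(self, small_cohort):
        subject = small_cohort[0]
        t = np.array([3.3371])
        obs = sample_observations(subject, t)
        interp = np.interp(t, subject.curve.times,
                           subject.curve.concentrations)
        assert obs.concentrations == pytest.approx(interp, rel=2e-3)


class TestCKDStages:
    @pytest.mark.parametrize("gfr,stage", [
        (15.0, "4"), (29.9, "4"), (30.0, "3B"), (44.9, "3B"),
        (45.0, "3A"), (60.0, "2"), (89.9, "2"), (90.0, "1"), (115.0, "1")])
    def test_stage_bins(self, gfr, stage):
        assert ckd_stage(gfr) == stage

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ckd_stage(14.0)

    def test_bins_partition_validated_range(self):
        edges = [b[1] for b in CKD_STAGE_BINS] + [CKD_STAGE_BINS[-1][2]]
        assert edges == [15.0, 30.0, 45.0, 60.0, 90.0, 115.0]


class TestErrorMetrics:
    def test_perfect_predictions(self):
        gfr = np.array([20.0, 50.0, 100.0])
        m = ErrorMetrics.from_errors(gfr, gfr)
        assert m.mae_mean == 0.0 and m.p15 == 0.0 and m.prop_gt5 == 0.0

    def test_p15_definition(self):
        gfr_true = np.array([100.0, 100.0])
        gfr_est = np.array([105.0, 120.0])  # 5% and 20% relative error
        m = ErrorMetrics.from_errors(gfr_true, gfr_est)
        assert m.p15 == pytest.approx(50.0)

    def test_matches_per_subject_recomputation(self, rng):
        gfr_true = rng.uniform(16, 110, 200)
        gfr_est = gfr_true * rng.uniform(0.7, 1.3, 200)
        m = ErrorMetrics.from_errors(gfr_true, gfr_est)
        ae = np.abs(gfr_est - gfr_true)
        re = 100 * ae / gfr_true
        assert m.mae_mean == pytest.approx(ae.mean())
        assert m.mae_sd == pytest.approx(ae.std(ddof=1))
        assert m.mre_mean == pytest.approx(re.mean())
        assert m.p15 == pytest.approx(100 * (re > 15).mean())
        assert m.prop_gt5 == pytest.approx(100 * (ae > 5).mean())
        assert m.prop_gt10 == pytest.approx(100 * (ae > 10).mean())
        # stage metrics cover every represented stage and add up to n
        assert sum(s.n for s in m.stages.values()) == 200

    def test_p15_invariant_to_unit_rescaling(self, rng):
        gfr_true = rng.uniform(16, 110, 50)
        gfr_est = gfr_true * rng.uniform(0.8, 1.2, 50)
        a = ErrorMetrics.from_errors(gfr_true, gfr_est, by_stage=False)
        b = ErrorMetrics.from_errors(gfr_true / 16.667, gfr_est / 16.667,
                                     by_stage=False)
        assert a.p15 == pytest.approx(b.p15)


class TestEvaluate:
    def test_zero_delta_equals_reference(self, small_cohort, fixture_prior):
        ref = evaluate_schedule(small_cohort, DEFAULT_SCHEDULE.as_array(),
                                fixture_prior)
        cells = evaluate_protocol(small_cohort,
                                  SingleShiftProtocol(1, (0.0,)),
                                  fixture_prior)
        assert cells[0.0].mae_mean == pytest.approx(ref.mae_mean)
        assert cells[0.0].p15 == pytest.approx(ref.p15)

    def test_infeasible_cell_reported_as_none(self, small_cohort,
                                              fixture_prior):
        cells = evaluate_protocol(small_cohort,
                                  SingleShiftProtocol(0, (-10.0, 2.0)),
                                  fixture_prior)
        assert cells[-10.0] is None
        assert cells[2.0] is not None

    def test_random_protocol_returns_metrics(self, small_cohort,
                                             fixture_prior):
        m = evaluate_protocol(small_cohort, RandomShiftProtocol(0.10, seed=3),
                              fixture_prior)
        assert m.n == len(small_cohort)
        assert np.isfinite(m.mae_mean)


class TestWindows:
    def test_all_below_threshold_spans_grid(self):
        t = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        lo, hi = window_from_single_shifts(2.0, t, np.full(5, 0.5), 2.0)
        assert (lo, hi) == (1.0, 3.0)

    def test_zero_threshold_gives_empty_window(self):
        t = np.array([1.0, 2.0, 3.0])
        with pytest.warns(RuntimeWarning):
            assert window_from_single_shifts(2.0, t, [0.5, 0.5, 0.5],
                                             0.0) is None

    def test_interpolated_crossings(self):
        """A MAE profile crossing the threshold at known positions yields
        hand-computable interpolated endpoints."""
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        mae = np.array([3.0, 1.0, 0.5, 1.0, 3.0])
        lo, hi = window_from_single_shifts(2.0, t, mae, 2.0)
        assert lo == pytest.approx(0.5)   # linear between (0,3) and (1,1)
        assert hi == pytest.approx(3.5)

    def test_rsd_window_matches_normal_quantiles_when_untruncated(self):
        """A window far wider than +/-1.645 sigma leaves the 90% interval
        at the closed-form normal quantiles."""
        schedule = SamplingSchedule((2.0,))
        out = window_from_rsd(schedule, rsd=0.10, windows_h=((0.5, 3.5),),
                              n_draws=200_000, seed=0)[0]
        z = norm.ppf(0.95)
        assert out["lo_h"] == pytest.approx(2.0 - z * 0.2, abs=0.01)
        assert out["hi_h"] == pytest.approx(2.0 + z * 0.2, abs=0.01)

    def test_rsd_window_stays_inside_truncation(self):
        out = window_from_rsd(DEFAULT_SCHEDULE, rsd=0.25, n_draws=100_000,
                              seed=1)
        for win, (lo, hi) in zip(out, DEFAULT_TRUNCATION_WINDOWS_H):
            assert lo <= win["lo_h"] <= win["hi_h"] <= hi
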