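"""Jump detection, changepoint segmentation, and dissolution metrics."""

import numpy as np
import pytest

import pelletmass as pm
from pelletmass.profile import estimate_series_noise


class TestDetectJumps:
    def test_gentle_monotone_series_has_none(self, make_series):
        sched = pm.DissolutionSchedule(50.0, phases=(pm.Phase(40.0, -0.5),))
        series = make_series(sched, 40.0, sigma=0.2, seed=1)
        assert pm.detect_jumps(series, min_drop=2.0) == []

    def test_scheduled_drop_found_once(self, make_series, fig_style_schedule):
        series = make_series(fig_style_schedule, 40.0, sigma=0.7, seed=2)
        jumps = pm.detect_jumps(series, min_drop=5.0)
        assert len(jumps) == 1
        assert jumps[0].time == pytest.approx(7.0, abs=0.25)
        assert jumps[0].dmass == pytest.approx(-50.0, abs=3.0)

    def test_two_jumps_ordered(self, make_series):
        sched = pm.DissolutionSchedule(
            100.0,
            phases=(pm.Phase(30.0, 0.0),),
            jumps=(pm.Jump(10.0, -20.0), pm.Jump(20.0, -30.0)),
        )
        series = make_series(sched, 30.0, sigma=0.3, seed=3)
        jumps = pm.detect_jumps(series, min_drop=5.0)
        assert len(jumps) == 2
        assert jumps[0].time < jumps[1].time
        assert jumps[0].dmass == pytest.approx(-20.0, abs=2.0)
        assert jumps[1].dmass == pytest.approx(-30.0, abs=2.0)

    def test_fast_ramp_is_not_a_jump(self, make_series):
        # a sustained -85 µg/min release drops ~14 µg per stroke, but the
        # steps form a phase longer than any single-stroke event
        sched = pm.DissolutionSchedule(
            170.0, phases=(pm.Phase(10.0, 0.0), pm.Phase(2.0, -85.0)), floor=0.0
        )
        series = make_series(sched, 14.0, sigma=0.3, seed=4)
        assert pm.detect_jumps(series, min_drop=5.0) == []


class TestSegmentProfile:
    def test_single_rate_recovered(self, make_series):
        sched = pm.DissolutionSchedule(100.0, phases=(pm.Phase(40.0, -1.0),))
        series = make_series(sched, 40.0, sigma=0.2, seed=5)
        segs = pm.segment_profile(series)
        assert len(segs) == 1
        assert segs[0].rate == pytest.approx(-1.0, rel=0.05)

    def test_flat_series_single_segment_near_zero_rate(self, make_series):
        sched = pm.DissolutionSchedule(30.0)
        series = make_series(sched, 40.0, sigma=0.2, seed=6)
        segs = pm.segment_profile(series)
        assert len(segs) == 1
        assert abs(segs[0].rate) < 3 * segs[0].rate_se

    def test_two_phase_break_and_rates(self, make_series):
        sched = pm.DissolutionSchedule(
            15.0, phases=(pm.Phase(30.0, -0.18), pm.Phase(8.0, -1.5)), floor=0.0
        )
        series = make_series(sched, 35.0, sigma=0.2, seed=7)
        segs = pm.segment_profile(series)
        assert len(segs) == 2
        assert segs[0].rate == pytest.approx(-0.18, rel=0.15)
        assert segs[1].rate == pytest.approx(-1.5, rel=0.15)
        assert segs[0].t_end == pytest.approx(30.0, abs=1.5)

    def test_time_shift_invariance(self, make_series):
        sched = pm.DissolutionSchedule(
            15.0, phases=(pm.Phase(30.0, -0.18), pm.Phase(8.0, -1.5)), floor=0.0
        )
        series = make_series(sched, 35.0, sigma=0.2, seed=8)
        shifted = pm.BuoyantMassSeries(
            series.time_min + 100.0, series.mass_ug, series.uncertainty_ug
        )
        a = pm.segment_profile(series)
        b = pm.segment_profile(shifted)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sb.t_start == pytest.approx(sa.t_start + 100.0, abs=1e-9)
            assert sb.rate == pytest.approx(sa.rate, rel=1e-9)

    def test_mass_rescaling_scales_rates(self, make_series):
        sched = pm.DissolutionSchedule(
            15.0, phases=(pm.Phase(30.0, -0.18), pm.Phase(8.0, -1.5)), floor=0.0
        )
        series = make_series(sched, 35.0, sigma=0.2, seed=9)
        scaled = pm.BuoyantMassSeries(
            series.time_min, 10.0 * series.mass_ug, 10.0 * series.uncertainty_ug
        )
        a = pm.segment_profile(series)
        b = pm.segment_profile(scaled)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sb.rate == pytest.approx(10.0 * sa.rate, rel=1e-9)

    def test_phase_count_recovery_rate(self, make_series):
        # with per-point noise at 0.2 µg the scheduled phase structure is
        # recovered in the vast majority of replicates
        two_phase = pm.DissolutionSchedule(
            15.0, phases=(pm.Phase(30.0, -0.18), pm.Phase(8.0, -1.5)), floor=0.0
        )
        flat = pm.DissolutionSchedule(30.0)
        hits = 0
        n = 20
        for seed in range(n):
            s2 = make_series(two_phase, 35.0, sigma=0.2, seed=100 + seed)
            s1 = make_series(flat, 35.0, sigma=0.2, seed=200 + seed)
            hits += len(pm.segment_profile(s2)) == 2 and len(pm.segment_profile(s1)) == 1
        assert hits >= int(0.9 * n)

    def test_too_few_points_reduces_max_segments(self, make_series):
        sched = pm.DissolutionSchedule(10.0, phases=(pm.Phase(2.0, -1.0),))
        series = make_series(sched, 2.0, sigma=0.0, seed=0)  # 11 points
        with pytest.warns(UserWarning, match="reducing max_segments"):
            segs = pm.segment_profile(series, max_segments=6)
        assert len(segs) >= 1


class TestComputeMetrics:
    def test_ghost_fraction_of_delayed_release_pellet(
        self, make_series, fig_style_schedule
    ):
        # 170 µg start, 15 µg insoluble residue -> ghost is ~9% of start
        series = make_series(fig_style_schedule, 40.0, sigma=0.0, seed=0)
        profile = pm.build_profile(series, jump_min_drop=5.0)
        m = profile.metrics
        assert m.start_mass == pytest.approx(170.0, abs=0.5)
        assert m.ghost_mass == pytest.approx(15.0, abs=0.5)
        assert m.ghost_fraction == pytest.approx(100 * 15 / 170, abs=0.3)
        assert round(m.ghost_fraction) == 9

    def test_fully_dissolving_series(self, make_series):
        sched = pm.DissolutionSchedule(
            50.0, phases=(pm.Phase(10.0, 0.0), pm.Phase(25.0, -2.0)), floor=0.0
        )
        series = make_series(sched, 35.0, sigma=0.2, seed=10)
        profile = pm.build_profile(series, dissolved_threshold=1.0)
        assert profile.metrics.ghost_mass == 0.0
        assert profile.metrics.completion_time == pytest.approx(35.0, abs=1.0)
        assert profile.metrics.onset_time == pytest.approx(10.0, abs=1.0)

    def test_constant_series_all_ghost(self, make_series):
        series = make_series(pm.DissolutionSchedule(30.0), 40.0, sigma=0.2, seed=11)
        profile = pm.build_profile(series)
        m = profile.metrics
        assert m.onset_time is None
        assert m.completion_time is None
        assert m.ghost_fraction == pytest.approx(100.0, abs=1.0)

    def test_percent_change(self):
        # a pellet growing from 22 to 25 µg has gained 14% of its mass
        assert round(pm.percent_change(22.0, 25.0)) == 14


class TestMassBalance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balance_on_jumpy_schedule(self, make_series, fig_style_schedule, seed):
        series = make_series(fig_style_schedule, 40.0, sigma=0.7, seed=seed)
        profile = pm.build_profile(series)
        residual, tol = pm.mass_balance(profile)
        assert abs(residual) <= 3 * max(tol, 0.7)

    def test_noise_estimator_on_trended_series(self, make_series):
        sched = pm.DissolutionSchedule(100.0, phases=(pm.Phase(40.0, -2.0),))
        series = make_series(sched, 40.0, sigma=0.5, seed=12)
        est = estimate_series_noise(series.mass_ug)
        assert est == pytest.approx(0.5, rel=0.3)
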