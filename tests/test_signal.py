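"""Filtering, baseline estimation, transit detection, mass conversion."""

import numpy as np
import pytest

import pelletmass as pm
from pelletmass.core import InvalidInputError
from pelletmass.signal import (
    ASYMMETRIC_PAIR,
    SINGLETON_PEAK,
    FrequencyTrace,
    default_cutoff,
)


def _flat_trace(n=5000, dt=0.002, value=474.25):
    t = np.arange(n) * dt
    return FrequencyTrace(t, np.full(n, value), dt)


class TestFrequencyTrace:
    def test_rejects_non_monotone_time(self):
        with pytest.raises(InvalidInputError, match="strictly increasing"):
            FrequencyTrace([0.0, 0.2, 0.1], [1.0, 1.0, 1.0], 0.1)

    def test_flags_gaps(self):
        t = np.array([0.0, 0.1, 0.2, 1.0, 1.1])
        tr = FrequencyTrace(t, np.ones(5), 0.1)
        assert tr.has_gaps()
        assert list(tr.gap_indices) == [3]


class TestLowpass:
    def test_constant_trace_unchanged(self):
        tr = _flat_trace()
        out = pm.lowpass(tr, 5.0)
        assert np.allclose(out.frequency_hz, tr.frequency_hz, atol=1e-9)
        assert out.frequency_hz.mean() == pytest.approx(474.25, rel=1e-9)

    def test_high_frequency_strongly_attenuated(self):
        dt = 0.002
        t = np.arange(20000) * dt
        tr = FrequencyTrace(t, np.sin(2 * np.pi * 100.0 * t), dt)
        out = pm.lowpass(tr, 5.0)
        # > 40 dB attenuation of a tone 20x above cutoff
        assert np.abs(out.frequency_hz[2000:-2000]).max() < 1e-2

    def test_zero_phase_preserves_peak_time(self, quiet_sensor, pump):
        sched = pm.DissolutionSchedule(180.0, phases=(pm.Phase(2.0, 0.0),))
        tr = pm.simulate_experiment(quiet_sensor, pump, sched, 0.5, seed=0)
        out = pm.lowpass(tr, default_cutoff(pump.transit_duration))
        # lobes are identical in depth; compare within the first lobe only
        first = tr.time_s < 2.75
        raw_peak = tr.time_s[first][np.argmin(tr.frequency_hz[first])]
        filt_peak = out.time_s[first][np.argmin(out.frequency_hz[first])]
        assert abs(raw_peak - filt_peak) <= 2 * tr.sample_interval

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidInputError):
            pm.lowpass(_flat_trace(), 300.0)


class TestBaseline:
    def test_flat_trace_baseline_equals_trace(self):
        tr = _flat_trace()
        base = pm.estimate_baseline(tr, window_s=1.0)
        assert np.allclose(base, tr.frequency_hz, atol=1e-12)

    def test_tracks_linear_drift(self):
        dt = 0.002
        t = np.arange(int(600 / dt)) * dt  # 10 minutes
        drift = 0.1 / 3600.0  # 0.1 Hz/h in Hz/s
        tr = FrequencyTrace(t, 474.25 + drift * t, dt)
        base = pm.estimate_baseline(tr, window_s=30.0)
        # fit away from the edge extrapolation zones
        interior = (t > 30.0) & (t < t[-1] - 30.0)
        slope = np.polyfit(t[interior], base[interior], 1)[0]
        assert slope == pytest.approx(drift, rel=0.01)

    def test_unbiased_by_transit_peaks(self, pump):
        sensor = pm.SensorModel(noise_sd=0.002)
        sched = pm.DissolutionSchedule(180.0, phases=(pm.Phase(10.0, 0.0),))
        tr = pm.simulate_experiment(sensor, pump, sched, 5.0, seed=4)
        filt = pm.lowpass(tr, default_cutoff(pump.transit_duration))
        base = pm.estimate_baseline(filt, window_s=30.0)
        err = np.abs(base - sensor.base_frequency)
        assert err.max() < 3 * sensor.noise_sd


class TestDetectTransits:
    def test_counts_match_schedule(self, quiet_sensor, pump):
        sched = pm.DissolutionSchedule(170.0, phases=(pm.Phase(5.0, 0.0),))
        tr = pm.simulate_experiment(quiet_sensor, pump, sched, 5.0, seed=0)
        filt = pm.lowpass(tr, default_cutoff(pump.transit_duration))
        base = pm.estimate_baseline(filt)
        pairs = pm.detect_transits(filt, base, pump=pump)
        assert len(pairs) == 30
        assert all(not p.quality_flags for p in pairs)
        # denser-than-fluid pellet: both extrema downward
        assert all(p.mean_height < 0 for p in pairs)

    def test_no_pellet_no_pairs(self, quiet_sensor, pump):
        sched = pm.DissolutionSchedule(0.0)
        tr = pm.simulate_experiment(quiet_sensor, pump, sched, 2.0, seed=0)
        filt = pm.lowpass(tr, default_cutoff(pump.transit_duration))
        base = pm.estimate_baseline(filt)
        assert pm.detect_transits(filt, base, pump=pump) == []

    def test_deleted_extremum_flags_singleton(self, quiet_sensor, pump):
        sched = pm.DissolutionSchedule(170.0, phases=(pm.Phase(5.0, 0.0),))
        tr = pm.simulate_experiment(quiet_sensor, pump, sched, 2.0, seed=0)
        # erase the second lobe of the second transit (stroke at 10-20 s,
        # transit at 12-13.5 s, second lobe after the midpoint)
        erase = (tr.time_s > 12.75) & (tr.time_s < 13.5)
        f = tr.frequency_hz.copy()
        f[erase] = quiet_sensor.base_frequency
        tr2 = FrequencyTrace(tr.time_s, f, tr.sample_interval)
        filt = pm.lowpass(tr2, default_cutoff(pump.transit_duration))
        base = pm.estimate_baseline(filt)
        pairs = pm.detect_transits(filt, base, pump=pump)
        flagged = [p for p in pairs if SINGLETON_PEAK in p.quality_flags]
        assert len(flagged) == 1
        assert 10.0 < flagged[0].time < 20.0

    def test_asymmetric_pair_flagged_but_kept(self):
        # hand-built residual: two same-sign lobes of very different depth
        dt = 0.002
        t = np.arange(int(10.0 / dt)) * dt
        resid = np.zeros(t.size)
        lobe = lambda c, d: -d * np.exp(-((t - c) ** 2) / (2 * 0.05**2))
        resid += lobe(2.4, 0.1) + lobe(3.1, 0.05)
        tr = FrequencyTrace(t, 474.25 + resid, dt)
        base = np.full(t.size, 474.25)
        pairs = pm.detect_transits(tr, base, 0.01, transit_duration=1.5)
        assert len(pairs) == 1
        assert ASYMMETRIC_PAIR in pairs[0].quality_flags
        assert pairs[0].mean_height == pytest.approx(-0.075, rel=0.05)


class TestToMassSeries:
    def test_reference_pairing(self, quiet_sensor, pump, cal):
        sched = pm.DissolutionSchedule(180.0, phases=(pm.Phase(5.0, 0.0),))
        tr = pm.simulate_experiment(quiet_sensor, pump, sched, 2.0, seed=0)
        filt = pm.lowpass(tr, default_cutoff(pump.transit_duration))
        base = pm.estimate_baseline(filt)
        series = pm.to_mass_series(pm.detect_transits(filt, base, pump=pump), cal)
        # -0.1 Hz mean height at K = 1.8e-3 g/Hz -> 180 µg
        assert series.mass_ug == pytest.approx(180.0, rel=5e-3)
        assert np.all(series.uncertainty_ug == pytest.approx(0.7))

    def test_empty_pairs_empty_series(self, cal):
        series = pm.to_mass_series([], cal)
        assert len(series) == 0

    def test_mean_of_noisy_replicates_converges(self, quiet_sensor, pump, cal):
        tr = pm.make_bead_fixture(
            quiet_sensor, pump, 50.0, n_transits=240, seed=8, height_jitter_ug=0.7
        )
        filt = pm.lowpass(tr, default_cutoff(pump.transit_duration))
        base = pm.estimate_baseline(filt)
        series = pm.to_mass_series(pm.detect_transits(filt, base, pump=pump), cal)
        assert len(series) == 240
        assert abs(series.mass_ug.mean() - 50.0) < 3 * 0.7 / np.sqrt(240)

    def test_mass_point_count_plus_flags_is_transit_count(self, pump, cal):
        sensor = pm.SensorModel()
        sched = pm.DissolutionSchedule(170.0, phases=(pm.Phase(10.0, 0.0),))
        tr = pm.simulate_experiment(sensor, pump, sched, 10.0, seed=2)
        filt = pm.lowpass(tr, default_cutoff(pump.transit_duration))
        base = pm.estimate_baseline(filt)
        pairs = pm.detect_transits(filt, base, pump=pump)
        series = pm.to_mass_series(pairs, cal)
        n_singleton = sum(1 for p in pairs if SINGLETON_PEAK in p.quality_flags)
        assert len(series) + n_singleton == 60
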