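"""Shared fixtures: sensors, pump, calibration, synthetic series, demo bundle."""

from __future__ import annotations

import numpy as np
import pytest

import pelletmass as pm
from pelletmass.io import calibrate_from_demo, make_demo_dataset


@pytest.fixture(scope="session")
def pump():
    return pm.PumpSchedule()


@pytest.fixture(scope="session")
def quiet_sensor():
    """Noise- and drift-free sensor for oracle comparisons."""
    return pm.SensorModel(noise_sd=0.0)


@pytest.fixture
def cal():
    """Reference point-mass calibration: K = 1.8e-3 g/Hz, 700 ng resolution.

    Function-scoped: estimate_resolution mutates the record in place.
    """
    return pm.PointMassCalibration(constant=1.8e-3, resolution=0.7e-6)


def series_from_schedule(
    sched: pm.DissolutionSchedule,
    duration_min: float,
    sigma: float = 0.0,
    seed: int = 0,
    cadence_min: float = 1.0 / 6.0,
) -> pm.BuoyantMassSeries:
    """Directly sampled mass series (one point per pump stroke) + noise.

    Points sit at the mid-transit time within each stroke (2.75 s in),
    matching where the full trace pipeline timestamps its measurements.
    """
    rng = np.random.default_rng(seed)
    offset_min = 2.75 / 60.0
    t = offset_min + np.arange(0.0, duration_min - offset_min, cadence_min)
    m = pm.pellet_mass_at(t, sched)
    if sigma > 0:
        m = m + rng.normal(0.0, sigma, t.size)
    u = np.full(t.size, max(sigma, 1e-6))
    return pm.BuoyantMassSeries(t, m, u)


@pytest.fixture(scope="session")
def make_series():
    return series_from_schedule


@pytest.fixture(scope="session")
def fig_style_schedule():
    """Delayed-release pellet with a mid-run fragmentation jump and a ghost.

    Flat 5 min at 170 µg, −33 µg/min for 2 min, a −50 µg jump at 7 min,
    then −2.5 µg/min decaying into a 15 µg insoluble floor.
    """
    return pm.DissolutionSchedule(
        170.0,
        phases=(pm.Phase(5.0, 0.0), pm.Phase(2.0, -33.0), pm.Phase(33.0, -2.5)),
        jumps=(pm.Jump(7.0, -50.0),),
        floor=15.0,
    )


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """Full demo bundle with calibrations, generated once per session."""
    out = tmp_path_factory.mktemp("demo")
    make_demo_dataset(out, seed=3)
    calibrate_from_demo(out)
    return out
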