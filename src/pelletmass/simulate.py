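"""Forward model of a vibrating-tube buoyant-mass dissolution experiment.

Generates synthetic resonance-frequency traces with the structure of the
real instrument's output: a baseline near 474.25 Hz set by the fluid
density, a pair of frequency extrema every pump stroke as the pellet
transits the two tine tips, samples every ~2 ms, i.i.d. Gaussian frequency
noise, optional slow linear drift, and pellet buoyant-mass trajectories
built from constant-rate phases, abrupt jump events and an insoluble
floor.  Also builds the two calibration fixtures: bulk-density holds at
known fluid densities and repeated transits of a reference microbead.

The sensitivity of the tube varies along the flow path with the square of
the local vibrational amplitude: zero at the mounted base and at the
midpoint between the tines, maximal at the two tine tips.  The mode weight
used here is ``w(s) = sin^2(2*pi*s)`` with path coordinate ``s`` running 0
(inlet base) -> 0.25 (first tip) -> 0.5 (midpoint) -> 0.75 (second tip) ->
1 (outlet base); any smooth function with those nodes would do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Fluid, InvalidInputError
from .signal import FrequencyTrace

#: default NaCl calibration densities, g/mL
DEFAULT_FIXTURE_DENSITIES = (1.00, 1.02, 1.04, 1.06, 1.08)


@dataclass
class SensorModel:
    """Physical parameters of the simulated vibrating-tube sensor.

    ``responsivity`` (Hz per gram of buoyant mass at a tine tip) is the
    reciprocal of the point-mass calibration constant K; the defaults
    (474.25 Hz baseline, K = 1.8e-3 g/Hz so a 180 µg pellet makes 0.1 Hz
    peaks) reproduce the working regime of the real instrument.  The
    default sample noise of 3.6 mHz is set so that the full measurement
    chain (filter, baseline, peak pairing) yields a replicate buoyant-mass
    spread of ~0.7 µg — the ~700 ng point-mass resolution such sensors
    achieve.  ``drift_rate`` is in Hz per hour, ``sample_interval`` in
    seconds.
    """

    base_frequency: float = 474.25
    density_slope: float = -300.0
    responsivity: float = 1.0 / 1.8e-3
    noise_sd: float = 0.0036
    drift_rate: float = 0.0
    sample_interval: float = 0.002
    reference_density: float = 1.000

    def __post_init__(self) -> None:
        if self.responsivity <= 0:
            raise InvalidInputError("responsivity must be > 0 Hz/g")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0 Hz")
        if self.sample_interval <= 0:
            raise InvalidInputError("sample_interval must be > 0 s")
        if self.density_slope >= 0:
            raise InvalidInputError("density_slope must be negative")


@dataclass
class PumpSchedule:
    """Back-and-forth pumping: one pellet transit per flow reversal.

    ``reversal_period`` is the stroke length in seconds (the instrument
    reverses every 10 s); ``transit_duration`` the time the pellet spends
    traversing the vibrating section within each stroke; ``phase_offset``
    when the transit starts within the stroke.
    """

    reversal_period: float = 10.0
    transit_duration: float = 1.5
    phase_offset: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.transit_duration <= self.reversal_period:
            raise InvalidInputError(
                "transit_duration must satisfy 0 < transit_duration <= reversal_period"
            )
        if not 0 <= self.phase_offset <= self.reversal_period - self.transit_duration:
            raise InvalidInputError(
                "phase_offset must keep the transit inside one stroke"
            )


@dataclass(frozen=True)
class Phase:
    """One constant-rate dissolution phase: duration (min), rate (µg/min)."""

    duration: float
    rate: float

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise InvalidInputError("phase duration must be >= 0 min")


@dataclass(frozen=True)
class Jump:
    """Instantaneous mass change: time (min), signed Δmass (µg)."""

    time: float
    dmass: float


@dataclass
class DissolutionSchedule:
    """Scheduled buoyant-mass trajectory: piecewise linear with jumps.

    The mass starts at ``initial_buoyant_mass`` (µg), follows the ordered
    constant-rate phases, holds after the last phase ends, adds every jump
    at its declared time, and is clipped from below at ``floor`` (µg) —
    the insoluble "ghost" residue.
    """

    initial_buoyant_mass: float
    phases: tuple[Phase, ...] = ()
    jumps: tuple[Jump, ...] = ()
    floor: float = 0.0

    def __post_init__(self) -> None:
        self.phases = tuple(
            p if isinstance(p, Phase) else Phase(*p) for p in self.phases
        )
        self.jumps = tuple(j if isinstance(j, Jump) else Jump(*j) for j in self.jumps)
        if self.floor < 0:
            raise InvalidInputError("floor must be >= 0 µg")
        if self.initial_buoyant_mass < self.floor:
            raise InvalidInputError("initial mass must be >= floor")

    @property
    def total_phase_duration(self) -> float:
        return sum(p.duration for p in self.phases)


def mode_weight(s):
    """Mass sensitivity along the flow path, ``w(s) = sin^2(2*pi*s)``.

    ``s`` in [0, 1]: 0 inlet base, 0.25 first tine tip, 0.5 midpoint,
    0.75 second tip, 1 outlet base.  Zero at the nodes, 1 at the tips.
    """
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise InvalidInputError("path coordinate s must lie in [0, 1]")
    w = np.sin(2.0 * np.pi * arr) ** 2
    return float(w) if np.isscalar(s) or arr.ndim == 0 else w


def pellet_mass_at(t_min, sched: DissolutionSchedule):
    """Scheduled buoyant mass (µg) at time(s) ``t_min`` (minutes)."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be >= 0 min")
    m = np.full(t.shape, sched.initial_buoyant_mass)
    start = 0.0
    for ph in sched.phases:
        m = m + ph.rate * np.clip(t - start, 0.0, ph.duration)
        start += ph.duration
    for j in sched.jumps:
        m = m + np.where(t >= j.time, j.dmass, 0.0)
    m = np.maximum(m, sched.floor)
    return float(m) if np.isscalar(t_min) else m


def _synthesize(
    sensor: SensorModel,
    pump: PumpSchedule,
    mass_ug_of_t_min,
    duration_s: float,
    rng: np.random.Generator,
    *,
    fluid: Fluid | None = None,
    transit_jitter_ug: float = 0.0,
    metadata: dict | None = None,
) -> FrequencyTrace:
    """Shared trace synthesis: baseline + drift + transits + noise."""
    n = int(round(duration_s / sensor.sample_interval))
    t = np.arange(n) * sensor.sample_interval
    base = sensor.base_frequency
    if fluid is not None:
        base = base + sensor.density_slope * (fluid.density - sensor.reference_density)
    f = base + sensor.drift_rate * (t / 3600.0)

    tau = np.mod(t - pump.phase_offset, pump.reversal_period)
    in_transit = tau < pump.transit_duration
    # one transit per *complete* pump stroke
    n_full_strokes = int(np.floor(duration_s / pump.reversal_period + 1e-9))
    in_transit &= np.floor(t / pump.reversal_period) < n_full_strokes
    s = np.where(in_transit, tau / pump.transit_duration, 0.0)
    w = np.where(in_transit, np.sin(2.0 * np.pi * s) ** 2, 0.0)

    m = np.asarray(mass_ug_of_t_min(t / 60.0), dtype=float)
    if transit_jitter_ug > 0:
        stroke = np.floor((t - pump.phase_offset) / pump.reversal_period).astype(int) + 1
        jitter = rng.normal(0.0, transit_jitter_ug, int(stroke.max()) + 1)
        m = m + jitter[stroke]
    f = f - sensor.responsivity * (m * 1e-6) * w
    if sensor.noise_sd > 0:
        f = f + rng.normal(0.0, sensor.noise_sd, n)

    meta = {"fluid_label": fluid.label if fluid is not None else ""}
    if metadata:
        meta.update(metadata)
    return FrequencyTrace(t, f, sensor.sample_interval, meta)


def simulate_experiment(
    sensor: SensorModel,
    pump: PumpSchedule,
    sched: DissolutionSchedule,
    duration_min: float,
    seed: int,
    fluid: Fluid | None = None,
) -> FrequencyTrace:
    """Simulate a full dissolution run and return the raw frequency trace.

    The trace is ``f(t) = base + drift*t - responsivity * m_b(t) * w(s(t))
    + noise`` with one transit per pump stroke, each producing two extrema
    of equal expected depth.  Deterministic for a given seed.
    """
    if duration_min <= 0:
        raise InvalidInputError("duration must be > 0 min")
    rng = np.random.default_rng(seed)
    return _synthesize(
        sensor,
        pump,
        lambda tm: pellet_mass_at(tm, sched),
        duration_min * 60.0,
        rng,
        fluid=fluid,
        metadata={"seed": seed, "kind": "dissolution-experiment"},
    )


def make_density_fixture(
    sensor: SensorModel,
    densities=DEFAULT_FIXTURE_DENSITIES,
    hold_min: float = 10.0,
    seed: int = 0,
) -> dict[float, FrequencyTrace]:
    """Bulk-density calibration fixture: one quiet hold per known density.

    Each trace is the density-shifted baseline plus noise (no pellet); its
    mean frequency sits on the line ``base + density_slope * (rho - ref)``.
    Returns a mapping density -> trace.
    """
    if hold_min <= 0:
        raise InvalidInputError("hold duration must be > 0 min")
    rng = np.random.default_rng(seed)
    n = int(round(hold_min * 60.0 / sensor.sample_interval))
    t = np.arange(n) * sensor.sample_interval
    out: dict[float, FrequencyTrace] = {}
    for rho in densities:
        f = np.full(
            n,
            sensor.base_frequency
            + sensor.density_slope * (rho - sensor.reference_density),
        )
        if sensor.noise_sd > 0:
            f = f + rng.normal(0.0, sensor.noise_sd, n)
        out[float(rho)] = FrequencyTrace(
            t.copy(),
            f,
            sensor.sample_interval,
            {"fluid_density_g_ml": float(rho), "kind": "density-hold", "seed": seed},
        )
    return out


def make_bead_fixture(
    sensor: SensorModel,
    pump: PumpSchedule,
    bead_buoyant_mass_ug: float,
    n_transits: int = 50,
    seed: int = 0,
    height_jitter_ug: float = 0.0,
) -> FrequencyTrace:
    """Point-mass calibration fixture: repeated transits of one microbead.

    A constant buoyant mass is passed through the sensor ``n_transits``
    times.  ``height_jitter_ug`` adds an independent Gaussian perturbation
    to the bead's apparent mass on each transit, emulating the
    transit-to-transit spread from which the mass resolution is estimated.
    """
    if n_transits < 2:
        raise InvalidInputError("need at least 2 transits for calibration")
    rng = np.random.default_rng(seed)
    duration_s = n_transits * pump.reversal_period
    return _synthesize(
        sensor,
        pump,
        lambda tm: np.full(np.shape(tm), float(bead_buoyant_mass_ug)),
        duration_s,
        rng,
        transit_jitter_ug=height_jitter_ug,
        metadata={
            "seed": seed,
            "kind": "bead-fixture",
            "bead_buoyant_mass_ug": float(bead_buoyant_mass_ug),
            "n_transits": int(n_transits),
        },
    )
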