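"""Sensor calibration: bulk fluid density, point mass, and resolution.

Two independent linear calibrations characterise the tube:

* **bulk density** — the mean resonance frequency recorded while the tube
  holds salt solutions of precisely known density falls on a line; its
  slope (Hz per g/mL) converts frequency to fluid density.
* **point mass** — a reference microbead of known mass and density is
  passed through the sensor repeatedly; the calibration constant K (g per
  Hz) is the bead's buoyant mass divided by its mean transit-peak height.
  The spread of those replicate heights, mapped through K, is the sensor's
  mass resolution (the real instrument achieves ~700 ng).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

from .core import (
    CalibrationError,
    DensityCalibration,
    Fluid,
    PelletState,
    PointMassCalibration,
    buoyant_mass,
)
from .signal import (
    FrequencyTrace,
    SINGLETON_PEAK,
    default_cutoff,
    detect_transits,
    estimate_baseline,
    lowpass,
)


def fit_density_calibration(
    mean_frequencies, known_densities
) -> DensityCalibration:
    """Ordinary least-squares line through (density, mean frequency).

    Needs at least two distinct densities.  The fitted record anchors its
    reference point at the mean calibration density (a point exactly on
    the line) and stores the density span, R² and residual SD.
    """
    f = np.asarray(mean_frequencies, dtype=float)
    rho = np.asarray(known_densities, dtype=float)
    if f.shape != rho.shape:
        raise CalibrationError("frequency and density lists differ in length")
    if np.unique(rho).size < 2:
        raise CalibrationError("need >= 2 distinct densities to fit a line")
    res = _stats.linregress(rho, f)
    ref_rho = float(np.mean(rho))
    ref_f = res.intercept + res.slope * ref_rho
    resid = f - (res.intercept + res.slope * rho)
    dof = rho.size - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return DensityCalibration(
        slope=float(res.slope),
        reference_frequency=float(ref_f),
        reference_density=ref_rho,
        valid_range=(float(rho.min()), float(rho.max())),
        r_squared=float(res.rvalue**2),
        residual_sd=residual_sd,
    )


def density_calibration_from_traces(
    traces: dict[float, FrequencyTrace]
) -> DensityCalibration:
    """Fit the density line from per-density hold traces (mean frequency)."""
    densities = sorted(traces)
    means = [float(np.mean(traces[rho].frequency_hz)) for rho in densities]
    return fit_density_calibration(means, densities)


def fit_point_mass_calibration(
    replicate_heights, bead: PelletState, fluid: Fluid
) -> PointMassCalibration:
    """Point-mass calibration constant from replicate bead transit heights.

    K = |bead buoyant mass| / |mean replicate height|, in g/Hz; the bead's
    buoyant mass follows from its known mass and density in the known
    fluid.  Uses magnitudes, so the result is independent of the peak sign
    convention.
    """
    h = np.asarray(replicate_heights, dtype=float)
    if h.size < 2:
        raise CalibrationError("need >= 2 replicate heights")
    mb = buoyant_mass(bead, fluid)  # µg
    if mb == 0:
        raise CalibrationError("bead buoyant mass is zero in this fluid")
    mean_h = np.mean(h)
    if mean_h == 0:
        raise CalibrationError("mean replicate height is zero")
    constant = abs(mb) * 1e-6 / abs(mean_h)
    return PointMassCalibration(
        constant=float(constant),
        bead_buoyant_mass=float(mb),
        n_replicates=int(h.size),
    )


def estimate_resolution(replicate_heights, cal: PointMassCalibration) -> float:
    """Mass resolution (g) from the spread of replicate bead heights.

    The width of the replicate-height distribution is taken as the sample
    standard deviation (1σ); resolution = K * SD.  Needs >= 3 replicates;
    the estimate is stored on the calibration record and returned.
    """
    h = np.asarray(replicate_heights, dtype=float)
    if h.size < 3:
        raise CalibrationError("need >= 3 replicate heights for a resolution estimate")
    sd = float(np.std(h, ddof=1))
    resolution = cal.constant * sd
    cal.resolution = resolution if resolution > 0 else None
    return resolution


def measure_replicate_heights(
    trace: FrequencyTrace,
    *,
    pump=None,
    transit_duration: float = 1.5,
    reversal_period: float = 10.0,
    cutoff_hz: float | None = None,
    min_prominence: float | None = None,
    baseline_window_s: float = 30.0,
) -> np.ndarray:
    """Per-transit mean peak heights (Hz) from a bead-fixture trace.

    Runs the standard measurement chain (low-pass filter, baseline,
    transit detection) and returns the mean height of every unflagged
    pair, for use by the point-mass and resolution fits.
    """
    if pump is not None:
        transit_duration = pump.transit_duration
        reversal_period = pump.reversal_period
    if cutoff_hz is None:
        cutoff_hz = default_cutoff(transit_duration)
    filtered = lowpass(trace, cutoff_hz)
    baseline = estimate_baseline(filtered, window_s=baseline_window_s)
    pairs = detect_transits(
        filtered,
        baseline,
        min_prominence,
        transit_duration=transit_duration,
        reversal_period=reversal_period,
    )
    return np.array(
        [p.mean_height for p in pairs if SINGLETON_PEAK not in p.quality_flags]
    )
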