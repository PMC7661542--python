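"""Transit-peak signal processing for vibrating-tube frequency traces.

Each passage of a pellet through the vibrating section is recorded as two
extrema in the resonance-frequency trace — one per tine tip, where the
vibrational amplitude (and hence the mass sensitivity) is maximal.  The
pipeline implemented here mirrors the instrument software: low-pass filter
the raw trace, estimate the slowly varying baseline, locate extrema, group
them into transit pairs, and convert per-pair mean heights into a
calibrated buoyant-mass time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sps

from .core import InvalidInputError, PointMassCalibration, shift_to_mass

#: quality flags attached to peak pairs
SINGLETON_PEAK = "singleton-peak"
ASYMMETRIC_PAIR = "asymmetric-pair"
LOW_PROMINENCE = "low-prominence"

#: pairs whose height asymmetry exceeds this fraction are flagged (but kept)
ASYMMETRY_FLAG_THRESHOLD = 0.25


@dataclass
class FrequencyTrace:
    """Uniformly sampled resonance-frequency time series.

    ``time_s`` must be strictly increasing.  Sampling gaps larger than five
    nominal sample intervals are flagged in ``gap_indices`` (index of the
    sample *after* each gap); gapped traces are resampled to a uniform grid
    before filtering.
    """

    time_s: np.ndarray
    frequency_hz: np.ndarray
    sample_interval: float
    metadata: dict = field(default_factory=dict)
    gap_indices: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        if self.time_s.shape != self.frequency_hz.shape:
            raise InvalidInputError("time and frequency arrays differ in length")
        if self.sample_interval <= 0:
            raise InvalidInputError("sample_interval must be > 0 s")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise InvalidInputError(
                    f"time values must be strictly increasing (violated at sample {bad})"
                )
            self.gap_indices = np.flatnonzero(dt > 5.0 * self.sample_interval) + 1
        else:
            self.gap_indices = np.empty(0, dtype=int)

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def duration(self) -> float:
        """Span of the trace in seconds."""
        if len(self) == 0:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0])

    def has_gaps(self) -> bool:
        return self.gap_indices.size > 0


@dataclass
class PeakPair:
    """One pellet transit: two frequency extrema relative to local baseline.

    Heights are signed (negative = downward = pellet denser than fluid);
    ``mean_height`` is the plain average of the two.  ``asymmetry`` records
    |h1 - h2| / max(|h1|, |h2|).  A lone extremum is emitted as a
    singleton-flagged pair with NaN in the second slot.
    """

    transit_index: int
    extremum_times: tuple[float, float]
    extremum_heights: tuple[float, float]
    baseline_value: float
    mean_height: float
    asymmetry: float
    quality_flags: frozenset[str] = frozenset()

    @property
    def time(self) -> float:
        """Representative transit time (s): mean of the extremum times."""
        t1, t2 = self.extremum_times
        return t1 if np.isnan(t2) else 0.5 * (t1 + t2)


@dataclass
class BuoyantMassSeries:
    """Timestamped calibrated buoyant masses with per-point uncertainty.

    Times in minutes, masses and uncertainties in µg.
    """

    time_min: np.ndarray
    mass_ug: np.ndarray
    uncertainty_ug: np.ndarray
    fluid_label: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.mass_ug = np.asarray(self.mass_ug, dtype=float)
        self.uncertainty_ug = np.asarray(self.uncertainty_ug, dtype=float)
        if not (self.time_min.shape == self.mass_ug.shape == self.uncertainty_ug.shape):
            raise InvalidInputError("series arrays differ in length")
        if self.time_min.size >= 2 and np.any(np.diff(self.time_min) <= 0):
            raise InvalidInputError("series times must be strictly increasing")

    def __len__(self) -> int:
        return self.time_min.size


def resample_uniform(trace: FrequencyTrace) -> FrequencyTrace:
    """Linearly interpolate a gapped trace onto a uniform grid."""
    if len(trace) < 2:
        return trace
    t0, t1 = trace.time_s[0], trace.time_s[-1]
    n = int(round((t1 - t0) / trace.sample_interval)) + 1
    grid = t0 + np.arange(n) * trace.sample_interval
    f = np.interp(grid, trace.time_s, trace.frequency_hz)
    return FrequencyTrace(grid, f, trace.sample_interval, dict(trace.metadata))


def lowpass(trace: FrequencyTrace, cutoff_hz: float) -> FrequencyTrace:
    """Zero-phase 4th-order Butterworth low-pass filter.

    Applied forward and backward (``sosfiltfilt``) so peak times are not
    shifted; DC gain is exactly 1 so baselines and bulk means survive.
    Gapped traces are resampled to a uniform grid first.
    """
    if trace.has_gaps():
        trace = resample_uniform(trace)
    nyquist = 0.5 / trace.sample_interval
    if not 0.0 < cutoff_hz < nyquist:
        raise InvalidInputError(
            f"cutoff must lie in (0, {nyquist:.6g}) Hz, got {cutoff_hz:.6g}"
        )
    sos = _sps.butter(4, cutoff_hz, fs=1.0 / trace.sample_interval, output="sos")
    filtered = _sps.sosfiltfilt(sos, trace.frequency_hz)
    return FrequencyTrace(
        trace.time_s.copy(), filtered, trace.sample_interval, dict(trace.metadata)
    )


def _robust_sd(x: np.ndarray) -> float:
    """Gaussian-consistent robust spread (1.4826 * MAD)."""
    if x.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _block_median(
    t: np.ndarray, f: np.ndarray, mask: np.ndarray, block: int
) -> tuple[np.ndarray, np.ndarray]:
    """Median of unmasked samples per block, with block-center times."""
    centers, medians = [], []
    for start in range(0, t.size, block):
        sl = slice(start, min(start + block, t.size))
        keep = mask[sl]
        if keep.any():
            centers.append(0.5 * (t[sl][0] + t[sl][-1]))
            medians.append(np.median(f[sl][keep]))
    return np.asarray(centers), np.asarray(medians)


def estimate_baseline(
    trace: FrequencyTrace, window_s: float = 30.0, n_passes: int = 2
) -> np.ndarray:
    """Slowly varying baseline (Hz) of a trace containing transit peaks.

    Robust rolling center: the trace is cut into windows of ``window_s``
    (default 30 s, three pump strokes), each summarised by its median, and
    the block medians are linearly interpolated back onto the sample grid.
    A second pass masks samples deviating from the first-pass baseline by
    more than 4 robust sigmas (the transit peaks) and recomputes the
    medians, so even deep peaks do not bias the result.  The window must be
    long against a transit and short against drift.
    """
    if window_s <= 0:
        raise InvalidInputError("baseline window must be > 0 s")
    t, f = trace.time_s, trace.frequency_hz
    if t.size == 0:
        return np.empty(0)
    block = max(int(round(window_s / trace.sample_interval)), 1)
    mask = np.ones(t.size, dtype=bool)
    baseline = np.full(t.size, np.median(f))
    for _ in range(max(n_passes, 1)):
        centers, medians = _block_median(t, f, mask, block)
        if centers.size == 0:
            break
        baseline = np.interp(t, centers, medians)
        resid = f - baseline
        thresh = max(4.0 * _robust_sd(resid), 1e-12)
        mask = np.abs(resid) <= thresh
        if mask.all():
            break
    return baseline


def default_prominence(residual: np.ndarray) -> float:
    """Default peak-detection threshold: 5x the robust noise SD.

    The robust SD (median absolute deviation, Gaussian-scaled) of the
    filtered, baseline-subtracted trace is insensitive to the sparse
    transit peaks themselves.  A relative floor of 1e-3 of the largest
    excursion keeps numerically quiet (noise-free) traces from resolving
    filter ripple as peaks.
    """
    rel_floor = 1e-3 * float(np.max(np.abs(residual), initial=0.0))
    return max(5.0 * _robust_sd(residual), rel_floor, 1e-12)


def default_cutoff(transit_duration: float) -> float:
    """Default low-pass cutoff (Hz) for a given transit duration.

    10 cycles per transit keeps the zero-phase (double-applied) filter's
    passband droop on the transit lobes below 0.5% while still strongly
    attenuating the sample-to-sample frequency-counter noise.
    """
    return 10.0 / transit_duration


def detect_transits(
    filtered: FrequencyTrace,
    baseline: np.ndarray,
    min_prominence: float | None = None,
    *,
    pump=None,
    transit_duration: float = 1.5,
    reversal_period: float = 10.0,
) -> list[PeakPair]:
    """Locate transit extrema and group them into peak pairs.

    Extrema of either sign whose prominence exceeds ``min_prominence``
    (default: 5x robust noise SD of the residual) are detected on the
    baseline-subtracted trace and assigned to pump-stroke windows of
    ``reversal_period``; within each window the two most prominent
    extrema are the tine-tip pair (a transit physically produces exactly
    two), provided they fall within ``transit_duration`` of each other.
    A lone extremum is emitted with the singleton-peak flag and pairs
    whose heights differ by more than 25% are flagged asymmetric but
    kept.  A pump schedule may be passed instead of the two scalars.
    """
    if pump is not None:
        transit_duration = pump.transit_duration
        reversal_period = pump.reversal_period
    if len(filtered) == 0:
        return []
    resid = filtered.frequency_hz - baseline
    if min_prominence is None:
        min_prominence = default_prominence(resid)
    if min_prominence <= 0:
        raise InvalidInputError("min_prominence must be > 0 Hz")
    down, _ = _sps.find_peaks(-resid, prominence=min_prominence)
    up, _ = _sps.find_peaks(resid, prominence=min_prominence)
    idx = np.unique(np.concatenate([down, up]))
    if idx.size == 0:
        return []
    times = filtered.time_s[idx]
    heights = resid[idx]
    windows = np.floor(times / reversal_period).astype(int)

    def _make_pair(k, sel) -> PeakPair:
        if sel.size == 1:
            t1, h1 = float(times[sel[0]]), float(heights[sel[0]])
            bval = float(np.interp(t1, filtered.time_s, baseline))
            return PeakPair(
                transit_index=k,
                extremum_times=(t1, float("nan")),
                extremum_heights=(h1, float("nan")),
                baseline_value=bval,
                mean_height=h1,
                asymmetry=0.0,
                quality_flags=frozenset({SINGLETON_PEAK}),
            )
        (a, b) = sel
        t1, t2 = float(times[a]), float(times[b])
        h1, h2 = float(heights[a]), float(heights[b])
        denom = max(abs(h1), abs(h2))
        asym = abs(h1 - h2) / denom if denom > 0 else 0.0
        flags = set()
        if asym > ASYMMETRY_FLAG_THRESHOLD:
            flags.add(ASYMMETRIC_PAIR)
        mid = 0.5 * (t1 + t2)
        bval = float(np.interp(mid, filtered.time_s, baseline))
        return PeakPair(
            transit_index=k,
            extremum_times=(t1, t2),
            extremum_heights=(h1, h2),
            baseline_value=bval,
            mean_height=0.5 * (h1 + h2),
            asymmetry=asym,
            quality_flags=frozenset(flags),
        )

    pairs: list[PeakPair] = []
    k = 0
    for win in np.unique(windows):
        in_win = np.flatnonzero(windows == win)
        # the transit's two tine-tip extrema dominate any filter ripple
        top = in_win[np.argsort(np.abs(heights[in_win]))[::-1][:2]]
        top = np.sort(top)
        if top.size == 2:
            h1, h2 = heights[top[0]], heights[top[1]]
            weaker, stronger = sorted((abs(h1), abs(h2)))
            incompatible = (
                times[top[1]] - times[top[0]] >= transit_duration
                or np.sign(h1) != np.sign(h2)  # tine tips shift the same way
                or weaker < 0.35 * stronger  # likely a noise extremum
            )
            if incompatible:
                keep = top[np.argmax(np.abs(heights[top]))]
                pairs.append(_make_pair(k, np.array([keep])))
                k += 1
                continue
        pairs.append(_make_pair(k, top))
        k += 1
    return pairs


def to_mass_series(
    pairs: list[PeakPair],
    cal: PointMassCalibration,
    *,
    include_flagged: bool = False,
    fluid_label: str = "",
) -> BuoyantMassSeries:
    """Convert peak pairs into a calibrated buoyant-mass series.

    One point per pair: time = mean extremum time (minutes), mass =
    -mean_height * K (µg, downward peaks positive).  Singleton-flagged
    pairs are excluded unless ``include_flagged``.  Per-point uncertainty
    is the calibration's mass resolution (µg), NaN if not yet estimated.
    """
    kept = [
        p
        for p in pairs
        if include_flagged or SINGLETON_PEAK not in p.quality_flags
    ]
    t = np.array([p.time / 60.0 for p in kept])
    m = np.array([shift_to_mass(p.mean_height, cal) for p in kept])
    u = np.full(
        t.size, cal.resolution * 1e6 if cal.resolution is not None else np.nan
    )
    return BuoyantMassSeries(t, m, u, fluid_label=fluid_label)
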