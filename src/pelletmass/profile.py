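"""Dissolution-profile analysis of calibrated buoyant-mass series.

A single-pellet dissolution profile is summarised as (i) abrupt *jump*
events — large mass losses completed within about one pump stroke, like a
coating fragment detaching — and (ii) piecewise-linear *phases*, each with
a constant release rate in µg/min.  Jumps are detected first and excised,
because a 50 µg loss in 10 s would otherwise dominate any least-squares
slope; the remaining sections are segmented by binary changepoint search
over a per-segment straight-line cost with a BIC-style penalty per extra
changepoint.  Summary metrics follow the vocabulary of dissolution
testing: starting mass, insoluble residual ("ghost") mass and fraction,
release onset time, and completion time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .core import InvalidInputError
from .signal import BuoyantMassSeries

#: minimum points per fitted segment
MIN_SEGMENT_POINTS = 3

#: per-changepoint penalty = PENALTY_PARAMS * sigma^2 * ln(n); a split adds
#: a slope, an intercept and a breakpoint location (3 parameters)
PENALTY_PARAMS = 3.0

#: default onset/stability floor on |rate|, µg/min
DEFAULT_RATE_FLOOR = 0.1


@dataclass(frozen=True)
class Segment:
    """One constant-rate phase fitted by least squares.

    ``intercept`` is the fitted mass (µg) at ``t_start``; the fitted line
    is ``mass(t) = intercept + rate * (t - t_start)``.
    """

    t_start: float
    t_end: float
    rate: float
    intercept: float
    n_points: int
    rate_se: float = 0.0
    resid_sd: float = 0.0

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def mass_at(self, t_min: float) -> float:
        return self.intercept + self.rate * (t_min - self.t_start)


@dataclass(frozen=True)
class JumpEvent:
    """Abrupt mass change: time (min), signed Δmass (µg), span (s)."""

    time: float
    dmass: float
    span_s: float


@dataclass(frozen=True)
class ProfileMetrics:
    start_mass: float  # µg
    ghost_mass: float  # µg
    ghost_fraction: float  # percent of starting mass
    onset_time: float | None  # min
    completion_time: float | None  # min


@dataclass
class DissolutionProfile:
    segments: list[Segment]
    jumps: list[JumpEvent]
    metrics: ProfileMetrics

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "t_start_min": s.t_start,
                    "t_end_min": s.t_end,
                    "rate_ug_per_min": s.rate,
                    "intercept_ug": s.intercept,
                    "n_points": s.n_points,
                    "rate_se_ug_per_min": s.rate_se,
                }
                for s in self.segments
            ],
            "jumps": [
                {"time_min": j.time, "dmass_ug": j.dmass, "span_s": j.span_s}
                for j in self.jumps
            ],
            "metrics": {
                "start_mass_ug": self.metrics.start_mass,
                "ghost_mass_ug": self.metrics.ghost_mass,
                "ghost_fraction_pct": self.metrics.ghost_fraction,
                "onset_time_min": self.metrics.onset_time,
                "completion_time_min": self.metrics.completion_time,
            },
        }


def percent_change(initial: float, final: float) -> float:
    """Relative change from ``initial`` to ``final`` in percent."""
    if initial == 0:
        raise InvalidInputError("percent change undefined for zero initial value")
    return 100.0 * (final - initial) / initial


def estimate_series_noise(mass_ug: np.ndarray) -> float:
    """Robust per-point noise SD (µg) from second differences.

    Second differences annihilate any locally linear trend; for i.i.d.
    noise their variance is 6 sigma^2, so sigma = 1.4826 * MAD(d2) / sqrt(6).
    """
    m = np.asarray(mass_ug, dtype=float)
    if m.size < 4:
        return 0.0
    d2 = np.diff(m, n=2)
    return float(1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0))


class _LineCost:
    """O(1) residual sum of squares of an OLS line over any index range."""

    def __init__(self, t: np.ndarray, m: np.ndarray):
        tc = t - t.mean()
        z = np.zeros(1)
        self.n = np.concatenate([z, np.cumsum(np.ones_like(tc))])
        self.st = np.concatenate([z, np.cumsum(tc)])
        self.sm = np.concatenate([z, np.cumsum(m)])
        self.stt = np.concatenate([z, np.cumsum(tc * tc)])
        self.stm = np.concatenate([z, np.cumsum(tc * m)])
        self.smm = np.concatenate([z, np.cumsum(m * m)])

    def rss(self, i, j):
        """RSS of the best-fit line over points [i, j); i, j may be arrays."""
        n = self.n[j] - self.n[i]
        st = self.st[j] - self.st[i]
        sm = self.sm[j] - self.sm[i]
        cxx = (self.stt[j] - self.stt[i]) - st * st / n
        cxy = (self.stm[j] - self.stm[i]) - st * sm / n
        cyy = (self.smm[j] - self.smm[i]) - sm * sm / n
        with np.errstate(divide="ignore", invalid="ignore"):
            out = cyy - np.where(cxx > 0, cxy * cxy / np.where(cxx > 0, cxx, 1.0), 0.0)
        return np.maximum(out, 0.0)


def _fit_segment(t: np.ndarray, m: np.ndarray) -> Segment:
    if t.size == 2:
        rate = (m[1] - m[0]) / (t[1] - t[0])
        return Segment(float(t[0]), float(t[-1]), float(rate), float(m[0]), 2)
    res = _stats.linregress(t, m)
    resid = m - (res.intercept + res.slope * t)
    resid_sd = float(np.sqrt(np.sum(resid**2) / max(t.size - 2, 1)))
    return Segment(
        t_start=float(t[0]),
        t_end=float(t[-1]),
        rate=float(res.slope),
        intercept=float(res.intercept + res.slope * t[0]),
        n_points=int(t.size),
        rate_se=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        resid_sd=resid_sd,
    )


def segment_profile(
    series: BuoyantMassSeries,
    max_segments: int = 6,
    penalty: float | None = None,
) -> list[Segment]:
    """Piecewise-linear changepoint segmentation of a mass series.

    Binary segmentation: repeatedly split the segment whose best split
    most reduces the total squared residual of per-segment least-squares
    lines, as long as the reduction exceeds the per-changepoint penalty
    (default ``3 * sigma^2 * ln(n)`` with sigma estimated robustly from
    second differences) and ``max_segments`` is not exceeded.  Returns the
    fitted segments in time order.
    """
    if max_segments < 1:
        raise InvalidInputError("max_segments must be >= 1")
    t = series.time_min
    m = series.mass_ug
    n = t.size
    if n < MIN_SEGMENT_POINTS:
        raise InvalidInputError(
            f"need >= {MIN_SEGMENT_POINTS} points to fit a dissolution profile"
        )
    if n < 2 * (max_segments + 1):
        reduced = max(1, n // (2 * MIN_SEGMENT_POINTS))
        warnings.warn(
            f"only {n} points: reducing max_segments from {max_segments} to {reduced}",
            stacklevel=2,
        )
        max_segments = reduced
    if penalty is None:
        sigma = estimate_series_noise(m)
        # floor keeps numerically quiet (noise-free) series from being
        # split on discretisation wiggles
        scale = max(float(np.max(np.abs(m))), 1.0)
        sigma = max(sigma, 1e-4 * scale)
        penalty = PENALTY_PARAMS * sigma**2 * np.log(n)

    cost = _LineCost(t, m)
    bounds = [0, n]  # segment boundaries (indices), always sorted
    while len(bounds) - 1 < max_segments:
        best_gain, best_k, best_pos = -np.inf, None, None
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < 2 * MIN_SEGMENT_POINTS:
                continue
            ks = np.arange(a + MIN_SEGMENT_POINTS, b - MIN_SEGMENT_POINTS + 1)
            split_cost = cost.rss(a, ks) + cost.rss(ks, b)
            j = int(np.argmin(split_cost))
            gain = float(cost.rss(a, b) - split_cost[j])
            if gain > best_gain:
                best_gain, best_k, best_pos = gain, int(ks[j]), (a, b)
        if best_k is None or best_gain <= penalty:
            break
        bounds = sorted(bounds + [best_k])
    return [
        _fit_segment(t[a:b], m[a:b]) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def detect_jumps(
    series: BuoyantMassSeries,
    min_drop: float | None = None,
    max_span_s: float = 15.0,
) -> list[JumpEvent]:
    """Detect abrupt mass-loss events completed within ``max_span_s``.

    A jump is a between-consecutive-points drop of at least ``min_drop``
    µg (default: 7x the median point uncertainty) completed within
    ``max_span_s``, judged as an *excess* over the local dissolution
    trend: the candidate step is compared against the median step on
    either side (the steeper of the two sides sets the trend), so the
    individual steps of a sustained fast-release ramp do not register as
    jumps while a one-stroke fragmentation event on top of any ramp does.
    Adjacent qualifying steps merge into one event; a merged event whose
    total span exceeds ``max_span_s`` is a fast *phase*, not a jump, and
    is left to the segmenter.
    """
    t = series.time_min
    m = series.mass_ug
    if t.size < 2:
        return []
    u_med = float(np.nanmedian(series.uncertainty_ug))
    if min_drop is None:
        if not np.isfinite(u_med) or u_med <= 0:
            raise InvalidInputError(
                "min_drop must be given when point uncertainties are unknown"
            )
        min_drop = 7.0 * u_med  # ~5x the sigma of a point-to-point step
    if np.isfinite(u_med) and min_drop <= u_med:
        raise InvalidInputError("min_drop must exceed the point uncertainty")

    span_min = max_span_s / 60.0
    d = np.diff(m)
    dt = np.diff(t)
    w = 5  # steps of local context on each side
    qualifies = np.zeros(d.size, dtype=bool)
    for i in range(d.size):
        if dt[i] > span_min + 1e-12:
            continue
        before = d[max(0, i - w) : i]
        after = d[i + 1 : i + 1 + w]
        med_before = float(np.median(before)) if before.size else 0.0
        med_after = float(np.median(after)) if after.size else 0.0
        trend = min(med_before, med_after)  # the steeper (more negative) side
        if d[i] - trend <= -min_drop:
            qualifies[i] = True

    jumps: list[JumpEvent] = []
    i = 0
    while i < d.size:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < d.size and qualifies[j + 1]:
            j += 1
        span = (t[j + 1] - t[i]) * 60.0
        if span <= max_span_s:
            t_mid = 0.5 * (t[i] + t[j + 1])
            # level on each side from a short local line fit evaluated at
            # the event midpoint, so the ongoing dissolution trend (which
            # continues up to the event) does not inflate the jump size
            lo, hi = max(0, i - w), min(t.size, j + 2 + w)
            level_before = _local_level(t[lo : i + 1], m[lo : i + 1], t_mid)
            level_after = _local_level(t[j + 1 : hi], m[j + 1 : hi], t_mid)
            jumps.append(
                JumpEvent(
                    time=float(t_mid),
                    dmass=float(level_after - level_before),
                    span_s=float(span),
                )
            )
        i = j + 1
    return jumps


def _local_level(ts: np.ndarray, ms: np.ndarray, at: float) -> float:
    """Level of a short stretch extrapolated to ``at`` (line fit, or mean)."""
    if ts.size >= 3:
        slope, intercept = np.polyfit(ts, ms, 1)
        return float(intercept + slope * at)
    return float(np.mean(ms))


def _split_at_jumps(
    series: BuoyantMassSeries, jumps: list[JumpEvent]
) -> list[np.ndarray]:
    """Index arrays of the inter-jump sections (jump spans excised)."""
    t = series.time_min
    keep = [np.arange(t.size)]
    for j in jumps:
        half = 0.5 * j.span_s / 60.0
        lo, hi = j.time - half, j.time + half
        new = []
        for idx in keep:
            left = idx[t[idx] <= lo + 1e-12]
            right = idx[t[idx] >= hi - 1e-12]
            if left.size:
                new.append(left)
            if right.size:
                new.append(right)
        keep = new
    return [idx for idx in keep if idx.size >= 2]


def compute_metrics(
    series: BuoyantMassSeries,
    segments: list[Segment],
    jumps: list[JumpEvent],
    dissolved_threshold: float | None = None,
    rate_floor: float = DEFAULT_RATE_FLOOR,
) -> ProfileMetrics:
    """Summary metrics of a segmented dissolution profile.

    * ``start_mass`` — median of the first segment's points when that
      segment is stable, otherwise the fitted mass at its start.  A
      segment counts as releasing when |rate| exceeds both ``rate_floor``
      and twice its own standard error (so spurious slopes fitted to flat
      noisy stretches do not register).
    * ``ghost_mass`` — same logic on the last segment; forced to 0 when
      the profile ends below ``dissolved_threshold`` (default 3x the
      median point uncertainty, i.e. 3x the mass resolution) *or* when
      the profile ends while still losing mass faster than ``rate_floor``
      (the pellet dropped below the detection limit mid-release, so no
      stable residue was ever observed).
    * ``ghost_fraction`` — 100 * ghost / start.
    * ``onset_time`` — first time release is evident: the earlier of the
      first jump and the start of the first segment with |rate| >
      ``rate_floor``; None for a flat profile.
    * ``completion_time`` — first time the measured mass falls below
      ``dissolved_threshold``; None if it never does.
    """
    if len(series) == 0 or not segments:
        raise InvalidInputError("cannot compute metrics on an empty profile")
    t = series.time_min
    m = series.mass_ug
    if dissolved_threshold is None:
        u_med = float(np.nanmedian(series.uncertainty_ug))
        dissolved_threshold = 3.0 * u_med if np.isfinite(u_med) and u_med > 0 else 0.0

    def _releasing(seg: Segment) -> bool:
        return abs(seg.rate) > max(rate_floor, 2.0 * seg.rate_se)

    def _segment_level(seg: Segment, at_start: bool) -> float:
        if not _releasing(seg):
            sel = (t >= seg.t_start - 1e-12) & (t <= seg.t_end + 1e-12)
            return float(np.median(m[sel]))
        return seg.mass_at(seg.t_start if at_start else seg.t_end)

    first, last = segments[0], segments[-1]
    start_mass = _segment_level(first, at_start=True)
    final_level = last.mass_at(last.t_end)
    # a series that ends mid-release dropped below the detection limit:
    # count it as dissolved only if the extrapolated crossing is imminent
    # (within 20% of the observed span), not a slow drift on a high level
    span = max(last.t_end - first.t_start, 1e-9)
    still_dissolving = (
        _releasing(last)
        and last.rate < 0
        and (final_level - dissolved_threshold) / -last.rate <= 0.2 * span
    )
    if final_level < dissolved_threshold or still_dissolving:
        ghost_mass = 0.0
    else:
        ghost_mass = _segment_level(last, at_start=False)

    onset_candidates = [s.t_start for s in segments if _releasing(s)]
    onset_candidates += [j.time for j in jumps]
    onset = min(onset_candidates) if onset_candidates else None

    below = np.flatnonzero(m < dissolved_threshold)
    if below.size:
        completion = float(t[below[0]])
    elif ghost_mass == 0.0 and still_dissolving and final_level > dissolved_threshold:
        # extrapolate the final release phase to the detection threshold
        completion = float(
            last.t_end + (dissolved_threshold - final_level) / last.rate
        )
    elif ghost_mass == 0.0:
        completion = float(last.t_end)
    else:
        completion = None

    frac = 100.0 * ghost_mass / start_mass if start_mass > 0 else float("nan")
    return ProfileMetrics(
        start_mass=float(start_mass),
        ghost_mass=float(ghost_mass),
        ghost_fraction=float(frac),
        onset_time=onset,
        completion_time=completion,
    )


def build_profile(
    series: BuoyantMassSeries,
    *,
    jump_min_drop: float | None = None,
    jump_max_span_s: float = 15.0,
    max_segments: int = 6,
    penalty: float | None = None,
    dissolved_threshold: float | None = None,
    rate_floor: float = DEFAULT_RATE_FLOOR,
) -> DissolutionProfile:
    """Full profile analysis: detect jumps, segment each section, summarise.

    Jump spans are excised and each remaining section segmented
    independently (``max_segments`` applies per section); the segments are
    concatenated in time order for the metrics.
    """
    try:
        jumps = detect_jumps(series, jump_min_drop, jump_max_span_s)
    except InvalidInputError:
        jumps = []  # no usable uncertainty and no explicit threshold
    sections = _split_at_jumps(series, jumps) if jumps else [np.arange(len(series))]
    segments: list[Segment] = []
    for idx in sections:
        if idx.size < MIN_SEGMENT_POINTS:
            sub_t, sub_m = series.time_min[idx], series.mass_ug[idx]
            segments.append(_fit_segment(sub_t, sub_m))
            continue
        sub = BuoyantMassSeries(
            series.time_min[idx],
            series.mass_ug[idx],
            series.uncertainty_ug[idx],
            series.fluid_label,
        )
        # silently cap segments on short sections instead of warning
        allowed = max(1, idx.size // (2 * MIN_SEGMENT_POINTS))
        segments.extend(segment_profile(sub, min(max_segments, allowed), penalty))
    segments.sort(key=lambda s: s.t_start)
    metrics = compute_metrics(
        series, segments, jumps, dissolved_threshold, rate_floor
    )
    return DissolutionProfile(segments=segments, jumps=jumps, metrics=metrics)


def mass_balance(profile: DissolutionProfile) -> tuple[float, float]:
    """Mass-balance residual of a profile and its aggregate uncertainty.

    The mass lost between start and ghost should be accounted for by the
    jumps plus the integrated segment rates (with gaps between adjacent
    segments — one sampling step, or an excised jump span — bridged at
    the mean of the neighbouring rates):

        residual = (start - ghost) + sum(rate * duration)
                   + sum(gap-bridged drops) + sum(jump Δm)

    which is ~0 for a consistent profile.  The aggregate uncertainty
    combines the start/ghost level uncertainties, each segment's
    integrated-rate uncertainty, and sqrt(2)x the per-segment residual SD
    per jump; compare |residual| against a small multiple of it.
    """
    segs, jumps, met = profile.segments, profile.jumps, profile.metrics
    gap_drop = sum(
        0.5 * (a.rate + b.rate) * max(b.t_start - a.t_end, 0.0)
        for a, b in zip(segs[:-1], segs[1:])
    )
    residual = (met.start_mass - met.ghost_mass) + sum(
        s.rate * s.duration for s in segs
    ) + gap_drop + sum(j.dmass for j in jumps)
    if met.ghost_mass == 0.0:
        # the unobserved tail below the detection limit is real mass loss
        # not covered by any fitted segment
        residual -= max(segs[-1].mass_at(segs[-1].t_end), 0.0)
    var = 0.0
    for s in (segs[0], segs[-1]):
        var += (1.2533 * s.resid_sd / np.sqrt(max(s.n_points, 1))) ** 2
    for s in segs:
        var += (s.rate_se * s.duration) ** 2
    for a, b in zip(segs[:-1], segs[1:]):
        # bridging a gap at the mean rate can miss up to half the rate
        # change over the gap (kink not centred in the gap)
        gap = max(b.t_start - a.t_end, 0.0)
        var += (0.5 * abs(b.rate - a.rate) * gap) ** 2
    point_sd = float(np.mean([s.resid_sd for s in segs])) if segs else 0.0
    var += len(jumps) * 2.0 * point_sd**2
    if met.ghost_mass == 0.0:
        # the sub-detection-limit tail is only known to about the
        # detection threshold, a few point-SDs in mass units
        var += (3.0 * point_sd) ** 2
    return float(residual), float(np.sqrt(var))
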