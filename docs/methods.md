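# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pelletmass`, and what the synthetic-data tests do and do not
establish about real instrument data.

## Sensor model

The vibrating tube is modelled as a linear sensor around its working
point. The resonance frequency is

    f(t) = f0 + s_ρ (ρ_fluid − ρ_ref) + d·t − R · m_b(t) · w(s(t)) + ε(t)

with `f0 = 474.25` Hz the baseline at the reference fluid density,
`s_ρ = −300` Hz/(g/mL) the bulk-density slope, `d` a linear drift (Hz/h,
default 0), `R` the point-mass responsivity (Hz per gram of buoyant mass
at a tine tip; default 1/1.8e-3, i.e. K = 1.8 mg/Hz so a 180 µg pellet
makes 0.1 Hz peaks), and `ε` i.i.d. Gaussian sample noise. The true
resonator law is nonlinear in the loaded mass, but over an 0.08 g/mL
density span and µg-scale point loads a linear model is accurate, which is
why both calibrations are straight-line fits.

**Mode weight.** Sensitivity varies along the flow path with the square of
the local vibration amplitude: zero at the mounted base and at the midpoint
between the tines, maximal at the two tips. Only these nodes are physically
constrained; we use the simplest smooth function with them,
`w(s) = sin²(2πs)` on the path coordinate `s ∈ [0, 1]` (tips at 0.25 and
0.75). The pellet advances linearly in `s` during each transit (constant
pump flow within a stroke), producing exactly two equal-depth extrema per
transit — the peak pair.

**Pump schedule.** Flow reverses every 10 s; the transit occupies
`transit_duration = 1.5` s of each stroke, starting 2 s in. The pellet's
dwell profile inside the tube is not constrained by any measurement, so
`transit_duration` is a free parameter; results depend on it only through
the filter cutoff and pairing window.

**Noise level.** The default sample noise is 3.6 mHz. This value was
calibrated once so that the *emergent* replicate spread of the full
measurement chain (filter → baseline → peak pairing → K) is ≈ 0.7 µg —
the ~700 ng point-mass resolution this sensor class achieves. Noise on
the frequency samples, not on the masses, is the physically meaningful
way to inject it, because every downstream stage then sees realistically
correlated errors.

**Dissolution schedules.** Pellet buoyant-mass trajectories are piecewise
linear with optional instantaneous jumps and a lower clip at an insoluble
`floor` (the "ghost"). The bundled demo schedules encode the archetypal
behaviours of commercial proton-pump-inhibitor pellets: immediate slow
two-phase release (−0.18 then −1.5 µg/min), delayed burst release (flat
~10 min, then complete loss in ≈2 min), a faster two-phase variant (−0.2
then −4.4 µg/min), a stomach-pH control that stays flat ≥ 40 min, and a
delayed-release pellet that sheds a 50 µg fragment in one pump stroke and
leaves a 15 µg ghost (≈9% of its 170 µg start). One narrative's printed
numbers are mutually inconsistent at the µg level (170 − 66 − 50 − 30 ≠
15); the demo schedule resolves this by letting the final −2.5 µg/min
phase decay into the 15 µg floor, which reproduces both the quoted
intermediate masses and the 15 µg endpoint.

## Signal processing

**Filtering** is a 4th-order Butterworth low-pass applied forward and
backward (`sosfiltfilt`), so peaks are not shifted in time and DC gain is
exactly 1. Because the zero-phase scheme doubles the effective order, the
default cutoff is `10/transit_duration` (≈6.7 Hz): at the spec's
single-pass-style `5/transit_duration` the doubled filter attenuated the
transit lobes by ≈5%, while at 10 the droop is <0.1% and sample noise is
still suppressed ~8-fold. The cutoff is configurable everywhere.

**Baseline** is a robust rolling centre: block medians over 30 s windows
(three pump strokes), linearly interpolated, with a second pass that masks
samples deviating by >4 robust σ (the transit peaks) before recomputing.
Transits occupy 15% of each stroke, so medians are immune to them; on
drift-only traces the baseline tracks the drift exactly away from the
first/last half-window.

**Transit detection** finds extrema of either sign with prominence above
5× the robust noise SD of the baseline-subtracted trace (with a relative
floor of 1e-3 of the largest excursion so that numerically quiet traces do
not resolve filter ripple). Extrema are grouped by pump-stroke window and
the two largest-|height| extrema form the tine-tip pair; a pair is
rejected in favour of a singleton when the extrema are farther apart than
one transit, have opposite signs, or the weaker is <35% of the stronger
(almost certainly a noise extremum). Singletons are flagged and excluded
from the mass series; pairs with >25% height asymmetry are flagged but
kept, since the two peaks are averaged unconditionally. Mean pair height ×
(−K) gives the buoyant mass; each point carries the calibration's
resolution as its uncertainty.

**Detection limit.** A peak must clear ~5σ of filtered noise, i.e. ≈4–5 µg
of buoyant mass under default conditions. Near this limit, selection and
ranking favour noise-inflated peaks, so measured masses are biased high
and terminal release rates flatten; rates fitted to segments whose masses
are below ~10× the resolution should be read qualitatively. The profile
metrics handle the end-state explicitly (below).

## Calibration

The density line is an ordinary least-squares fit of mean hold frequency
vs. known density, anchored at the mean calibration density, storing slope,
span, R², and residual SD. The point-mass constant is K = |bead buoyant
mass| / |mean replicate height| (sign-convention invariant); the bead's
buoyant mass comes from its known mass and density through the buoyancy
relation. "Width of the replicate-height distribution" is taken as the
sample standard deviation (1σ); resolution = K × SD. Simulated noiseless
fixtures recover both generator parameters to ≤0.1%, and to ≤1% at 1 mHz
sample noise.

## Profile analysis

**Jumps first.** Abrupt events are detected before any slope fitting
because a 50 µg/10 s event would dominate a least-squares line. A
consecutive-point drop qualifies if its *excess* over the local trend (the
median step on the steeper of the two flanking sides, 5 steps each)
exceeds `min_drop` (default 7× the point uncertainty, ≈5σ of a
point-to-point difference) and completes within `max_span_s` (default
15 s, i.e. one pump stroke plus slack). Judging the excess rather than
the raw step keeps a sustained −85 µg/min burst phase — 14 µg per stroke
— from being shredded into jump events; merged candidate runs longer than
`max_span_s` are likewise left to the segmenter as fast phases. The
reported Δmass is the difference of short local line fits extrapolated to
the event midpoint, so ongoing dissolution up to the event does not
inflate the jump size; the residual ambiguity (the jump's exact time
within one stroke) is a fraction of one stroke's trend.

**Segmentation** is binary: repeatedly split the segment whose best
changepoint most reduces the total squared residual of per-segment OLS
lines, while the reduction exceeds a BIC-style penalty `3 σ² ln n` (three
parameters per extra changepoint: slope, intercept, breakpoint). σ is
estimated from second differences (which annihilate local trends) via the
MAD, with a floor of 1e-4 of the mass scale so noise-free series are not
split on discretisation wiggle. Minimum segment length is 3 points;
`max_segments` caps the search and is silently reduced on short sections.
The penalty constant is a design choice — no objective phase-boundary
criterion exists for these profiles — and is configurable. Under the
reference two-phase conditions (−0.18/−1.5 µg/min, break at 30 min,
σ = 0.2 µg, 10 s cadence) the structure is recovered in ≥90% of seeded
replicates. Jump spans are excised and sections segmented independently.

**Metrics.** `start_mass` is the median of the first segment's points if
that segment is stable, else the fitted mass at its start; a segment
counts as releasing only when |rate| exceeds both `rate_floor` (default
0.1 µg/min) and 2× its own standard error, so spurious slopes on flat
noisy stretches do not register. `ghost_mass` applies the same logic to
the last segment, and is 0 when the profile ends below
`dissolved_threshold` (default 3× resolution) or ends mid-release with the
extrapolated threshold crossing imminent (within 20% of the observed span)
— the pellet dropped below the detection limit while dissolving, so no
residue was observed. `ghost_fraction = 100·ghost/start`; `onset_time` is
the earlier of the first jump and the first releasing segment;
`completion_time` is the first sub-threshold point, or the extrapolated
crossing for mid-release endings. The mass-balance diagnostic compares
start − ghost against integrated segment rates plus jumps, bridging
inter-segment gaps at the mean neighbouring rate; its aggregate
uncertainty includes level SEs, rate SEs × durations, a half-rate-change
term per gap (the kink's position within a gap is unknown), √2 point-SDs
per jump, and a detection-limit term when the tail was unobserved.

## Reproducibility and problem sizes

All randomness flows through explicit integer seeds into
`numpy.random.default_rng`; identical seeds give byte-identical traces and
pipeline outputs (outputs are serialized at 12 significant digits, and run
logs contain no timestamps). The test suite and acceptance script use
40-minute experiments at 2 ms sampling (1.2M samples, 240 transits),
10-minute calibration holds, 200-transit bead fixtures, a 4-hour
slow-uptake run, and 100-replicate segmentation studies — sizes chosen to
exercise every stage at full sampling density while keeping a complete run
in tens of seconds.

## What the synthetic tests do not show

The generator emulates baseline, density response, transit shape, Gaussian
noise, and linear drift. Real traces additionally contain air bubbles,
pellet collisions with the tube wall, flow-rate variation within a stroke,
temperature-driven baseline wander, and occasional missed reversals — all
of which appear as non-Gaussian artifacts the quality flags only partially
capture. Passing the suite therefore demonstrates correctness of the
analysis chain under the stated noise model, not robustness to every
instrument pathology. Temperature compensation, nonlinear resonator
calibration, multi-pellet disambiguation, solubility-product estimation,
and in-vitro/in-vivo correlation modelling are out of scope.
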