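"""File formats, run configuration, and the end-to-end pipeline.

Traces travel as two-column CSV (``time_s,frequency_hz``), peak tables and
mass series as tidy CSV, calibrations and profiles as JSON, run
configuration as YAML.  Numbers are serialized with 12 significant digits
so simulate -> write -> read round trips are lossless at working
precision, and a pipeline run is byte-reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (
    density_calibration_from_traces,
    estimate_resolution,
    fit_point_mass_calibration,
    measure_replicate_heights,
)
from .core import Fluid, InvalidInputError, PelletState, PointMassCalibration
from .profile import DissolutionProfile, build_profile
from .signal import (
    BuoyantMassSeries,
    FrequencyTrace,
    PeakPair,
    SINGLETON_PEAK,
    default_cutoff,
    detect_transits,
    estimate_baseline,
    lowpass,
    to_mass_series,
)
from .simulate import (
    DissolutionSchedule,
    Jump,
    Phase,
    PumpSchedule,
    SensorModel,
    make_bead_fixture,
    make_density_fixture,
    simulate_experiment,
)

_FLOAT_FMT = "%.12g"


class TraceFormatError(InvalidInputError):
    """A trace file does not conform to the CSV contract."""


class MissingCalibrationError(FileNotFoundError):
    """No point-mass calibration available for the requested run."""


class EmptyProfileError(InvalidInputError):
    """The trace yielded no usable transits, so no profile exists."""


# ---------------------------------------------------------------------------
# traces


def read_trace(path: str | Path) -> FrequencyTrace:
    """Read a ``time_s,frequency_hz`` CSV into a validated trace.

    Malformed rows are rejected with their (1-based, header-inclusive)
    line numbers; time must be strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_s", "frequency_hz"} - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("time_s", "frequency_hz"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        nan_rows = np.flatnonzero(df[col].isna().to_numpy())
        bad = np.concatenate([bad, nan_rows])
        if bad.size:
            line = int(bad.min()) + 2  # +1 header, +1 one-based
            raise TraceFormatError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = vals
    t = df["time_s"].to_numpy(float)
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.argmax(dt <= 0)) + 3
            raise TraceFormatError(
                f"{path}: time_s not strictly increasing at line {line}"
            )
        interval = float(np.median(dt))
    else:
        interval = 1.0
    return FrequencyTrace(
        t, df["frequency_hz"].to_numpy(float), interval, {"source": str(path)}
    )


def write_trace(trace: FrequencyTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "frequency_hz": trace.frequency_hz}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_peak_table(pairs: list[PeakPair], path: str | Path) -> None:
    rows = [
        {
            "transit_index": p.transit_index,
            "time_s": p.time,
            "mean_height_hz": p.mean_height,
            "baseline_hz": p.baseline_value,
            "flags": ";".join(sorted(p.quality_flags)),
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows, columns=["transit_index", "time_s", "mean_height_hz", "baseline_hz", "flags"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_mass_series(series: BuoyantMassSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": series.time_min * 60.0,
            "buoyant_mass_ug": series.mass_ug,
            "uncertainty_ug": series.uncertainty_ug,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_mass_series(path: str | Path, fluid_label: str = "") -> BuoyantMassSeries:
    df = pd.read_csv(path)
    missing = {"time_s", "buoyant_mass_ug"} - set(df.columns)
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {sorted(missing)}")
    u = (
        df["uncertainty_ug"].to_numpy(float)
        if "uncertainty_ug" in df.columns
        else np.full(len(df), np.nan)
    )
    return BuoyantMassSeries(
        df["time_s"].to_numpy(float) / 60.0,
        df["buoyant_mass_ug"].to_numpy(float),
        u,
        fluid_label=fluid_label,
    )


def write_profile(profile: DissolutionProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile.to_dict(), indent=2) + "\n")


def write_segments_csv(profile: DissolutionProfile, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "t_start_min": s.t_start,
                "t_end_min": s.t_end,
                "rate_ug_per_min": s.rate,
                "intercept_ug": s.intercept,
                "n_points": s.n_points,
            }
            for s in profile.segments
        ],
        columns=["t_start_min", "t_end_min", "rate_ug_per_min", "intercept_ug", "n_points"],
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run.

    ``None`` for cutoff/prominence/penalty/thresholds means "use the
    data-driven default" of the corresponding stage.  Round-trips
    losslessly through YAML.
    """

    trace_path: str
    calibration_path: str
    out_dir: str
    cutoff_hz: float | None = None
    min_prominence: float | None = None
    baseline_window_s: float = 30.0
    reversal_period: float = 10.0
    transit_duration: float = 1.5
    phase_offset: float = 2.0
    jump_min_drop: float | None = None
    jump_max_span_s: float = 15.0
    max_segments: int = 6
    penalty: float | None = None
    dissolved_threshold: float | None = None
    rate_floor: float = 0.1
    fluid_label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_window_s", "reversal_period", "transit_duration",
                     "jump_max_span_s"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        for name in ("cutoff_hz", "min_prominence", "jump_min_drop", "penalty",
                     "dissolved_threshold"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidInputError(f"{name} must be > 0 when given")
        if self.max_segments < 1:
            raise InvalidInputError("max_segments must be >= 1")
        if self.rate_floor < 0 or self.phase_offset < 0:
            raise InvalidInputError("rate_floor and phase_offset must be >= 0")

    def pump(self) -> PumpSchedule:
        return PumpSchedule(
            self.reversal_period, self.transit_duration, self.phase_offset
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> DissolutionProfile:
    """Raw trace -> filtered trace -> peaks -> mass series -> profile.

    Writes every intermediate artifact plus a run log into
    ``config.out_dir`` and returns the profile.  Identical config (and
    inputs) gives byte-identical outputs.
    """
    cal_path = Path(config.calibration_path)
    if not cal_path.exists():
        raise MissingCalibrationError(
            f"no calibration at {cal_path}; run `pelletmass calibrate-density` "
            "and `pelletmass calibrate-mass` first"
        )
    cal = PointMassCalibration.from_json(cal_path)
    trace = read_trace(config.trace_path)
    if len(trace) == 0:
        raise EmptyProfileError(f"{config.trace_path}: trace is empty")

    cutoff = config.cutoff_hz or default_cutoff(config.transit_duration)
    filtered = lowpass(trace, cutoff)
    baseline = estimate_baseline(filtered, window_s=config.baseline_window_s)
    pairs = detect_transits(
        filtered,
        baseline,
        config.min_prominence,
        transit_duration=config.transit_duration,
        reversal_period=config.reversal_period,
    )
    series = to_mass_series(pairs, cal, fluid_label=config.fluid_label)
    if len(series) < 3:
        raise EmptyProfileError(
            f"{config.trace_path}: only {len(series)} usable transits; "
            "no dissolution profile can be fitted"
        )
    profile = build_profile(
        series,
        jump_min_drop=config.jump_min_drop,
        jump_max_span_s=config.jump_max_span_s,
        max_segments=config.max_segments,
        penalty=config.penalty,
        dissolved_threshold=config.dissolved_threshold,
        rate_floor=config.rate_floor,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trace(filtered, out / "filtered_trace.csv")
    write_peak_table(pairs, out / "peaks.csv")
    write_mass_series(series, out / "mass_series.csv")
    write_profile(profile, out / "profile.json")
    write_segments_csv(profile, out / "segments.csv")
    n_flagged = sum(1 for p in pairs if p.quality_flags)
    log = {
        "pelletmass_version": __version__,
        "config": dataclasses.asdict(config),
        "effective_cutoff_hz": cutoff,
        "n_samples": len(trace),
        "n_pairs": len(pairs),
        "n_flagged_pairs": n_flagged,
        "n_mass_points": len(series),
        "n_segments": len(profile.segments),
        "n_jumps": len(profile.jumps),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return profile


# ---------------------------------------------------------------------------
# demo dataset


#: fluids used by the demo experiments (density in g/mL)
DEMO_FLUIDS = {
    "sif_ph7": Fluid(1.004, "simulated intestinal fluid pH 7.0"),
    "sgf_ph2": Fluid(1.008, "simulated stomach fluid pH 2.0"),
}

#: reference microbead used for the demo point-mass calibration
DEMO_BEAD = PelletState(absolute_mass=300.0, density=1.5)
DEMO_BEAD_FLUID = Fluid(1.000, "water")


def demo_schedules() -> dict[str, dict]:
    """The bundled synthetic single-pellet experiments.

    Each entry mimics a narrative archetype of proton-pump-inhibitor
    pellets: an immediately but slowly releasing two-phase pellet
    (omeprazole-like), a delayed burst-release pellet (lansoprazole-like),
    a two-phase pellet with a fast second phase (esomeprazole-like), an
    enteric-protected flat control at stomach pH, and a pellet showing a
    mid-run 50 µg fragmentation jump and an insoluble 15 µg ghost.
    """
    return {
        "omeprazole_ph7": {
            "schedule": DissolutionSchedule(
                15.0, phases=(Phase(30.0, -0.18), Phase(8.0, -1.5)), floor=0.0
            ),
            "fluid": "sif_ph7",
            "duration_min": 40.0,
        },
        "lansoprazole_ph7": {
            "schedule": DissolutionSchedule(
                170.0, phases=(Phase(10.0, 0.0), Phase(2.5, -85.0)), floor=0.0
            ),
            "fluid": "sif_ph7",
            "duration_min": 16.0,
        },
        "esomeprazole_ph7": {
            "schedule": DissolutionSchedule(
                25.0, phases=(Phase(15.0, -0.2), Phase(6.0, -4.4)), floor=0.0
            ),
            "fluid": "sif_ph7",
            "duration_min": 25.0,
        },
        "esomeprazole_ph2": {
            "schedule": DissolutionSchedule(30.0, phases=(Phase(45.0, 0.0),), floor=0.0),
            "fluid": "sgf_ph2",
            "duration_min": 45.0,
        },
        "lansoprazole_gastric": {
            "schedule": DissolutionSchedule(
                170.0,
                phases=(Phase(5.0, 0.0), Phase(2.0, -33.0), Phase(33.0, -2.5)),
                jumps=(Jump(7.0, -50.0),),
                floor=15.0,
            ),
            "fluid": "sgf_ph2",
            "duration_min": 40.0,
        },
    }


def _schedule_dict(sched: DissolutionSchedule) -> dict:
    return {
        "initial_buoyant_mass_ug": sched.initial_buoyant_mass,
        "phases": [{"duration_min": p.duration, "rate_ug_per_min": p.rate} for p in sched.phases],
        "jumps": [{"time_min": j.time, "dmass_ug": j.dmass} for j in sched.jumps],
        "floor_ug": sched.floor,
    }


def make_demo_dataset(
    out_dir: str | Path,
    seed: int = 0,
    sensor: SensorModel | None = None,
    pump: PumpSchedule | None = None,
) -> dict:
    """Generate and write the full demo fixture bundle.

    Emits the density-calibration holds (plus a manifest CSV mapping file
    to density), a 200-transit bead fixture, and the five demo pellet
    experiments, together with a ``manifest.json`` recording every true
    parameter for downstream testing.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sensor = sensor or SensorModel()
    pump = pump or PumpSchedule()
    rng = np.random.default_rng(seed)

    density_traces = make_density_fixture(sensor, seed=int(rng.integers(2**31)))
    dens_rows = []
    for rho, tr in density_traces.items():
        name = f"density_{rho:.3f}.csv"
        write_trace(tr, out / name)
        dens_rows.append({"path": name, "density_g_ml": rho})
    pd.DataFrame(dens_rows).to_csv(out / "density_manifest.csv", index=False)

    from .core import buoyant_mass as _bm

    bead_mb = _bm(DEMO_BEAD, DEMO_BEAD_FLUID)
    bead_trace = make_bead_fixture(
        sensor,
        pump,
        bead_mb,
        n_transits=200,
        seed=int(rng.integers(2**31)),
    )
    write_trace(bead_trace, out / "bead.csv")

    experiments = {}
    for name, spec in demo_schedules().items():
        fluid = DEMO_FLUIDS[spec["fluid"]]
        exp_seed = int(rng.integers(2**31))
        trace = simulate_experiment(
            sensor, pump, spec["schedule"], spec["duration_min"], exp_seed, fluid
        )
        fname = f"{name}.csv"
        write_trace(trace, out / fname)
        experiments[name] = {
            "path": fname,
            "fluid": spec["fluid"],
            "fluid_density_g_ml": fluid.density,
            "duration_min": spec["duration_min"],
            "seed": exp_seed,
            "schedule": _schedule_dict(spec["schedule"]),
        }

    manifest = {
        "seed": seed,
        "sensor": dataclasses.asdict(sensor),
        "pump": dataclasses.asdict(pump),
        "bead": {
            "absolute_mass_ug": DEMO_BEAD.absolute_mass,
            "density_g_ml": DEMO_BEAD.density,
            "fluid_density_g_ml": DEMO_BEAD_FLUID.density,
            "buoyant_mass_ug": bead_mb,
            "n_transits": 200,
            "path": "bead.csv",
        },
        "density_fixture": dens_rows,
        "experiments": experiments,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def calibrate_from_demo(demo_dir: str | Path) -> PointMassCalibration:
    """Run both calibrations on a demo bundle; returns the point-mass record.

    Also writes ``density_calibration.json`` and ``mass_calibration.json``
    into the bundle directory.
    """
    demo_dir = Path(demo_dir)
    manifest = json.loads((demo_dir / "manifest.json").read_text())
    pump = PumpSchedule(**manifest["pump"])

    traces = {
        row["density_g_ml"]: read_trace(demo_dir / row["path"])
        for row in manifest["density_fixture"]
    }
    dcal = density_calibration_from_traces(traces)
    dcal.to_json(demo_dir / "density_calibration.json")

    bead_info = manifest["bead"]
    bead = PelletState(bead_info["absolute_mass_ug"], bead_info["density_g_ml"])
    bead_fluid = Fluid(bead_info["fluid_density_g_ml"], "water")
    heights = measure_replicate_heights(
        read_trace(demo_dir / bead_info["path"]), pump=pump
    )
    mcal = fit_point_mass_calibration(heights, bead, bead_fluid)
    estimate_resolution(heights, mcal)
    mcal.to_json(demo_dir / "mass_calibration.json")
    return mcal
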