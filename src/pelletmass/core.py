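"""Buoyant-mass physics and linear sensor-calibration models.

A fluid-filled glass tube bent into a tuning-fork shape and driven at its
resonance frequency acts as a mass sensor: filling it with a denser fluid
lowers the resonance frequency in proportion to the fluid density, and a
particle transiting the vibrating section momentarily shifts the frequency
in proportion to the particle's *buoyant mass*

    m_b = m * (1 - rho_fluid / rho_pellet) = V * (rho_pellet - rho_fluid)

where ``m`` is the absolute (in vacuo) mass of the particle, ``V`` its
volume and ``rho`` the densities.  A pellet denser than the carrier fluid
adds mass to the tube and pulls the frequency *down*; a pellet lighter than
the fluid pushes it *up*.  This module holds the unit-consistent domain
types, the buoyant-mass relation, the two linear calibration models
(bulk-density and point-mass) and the two-fluid mass/volume/density solver.

Internal units are fixed: mass in µg, volume in nL, density in g/mL,
frequency in Hz.  With these units 1 µg / (1 g/mL) = 1 nL, so no conversion
factors appear in the buoyancy algebra.  The point-mass calibration
constant is kept in g/Hz (the instrument's natural unit); conversion to µg
happens where peak heights are turned into masses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path


class InvalidInputError(ValueError):
    """A physically meaningless input (non-positive density, bad range)."""


class CalibrationError(ValueError):
    """A calibration record is degenerate or underdetermined."""


class DegenerateSystemError(ValueError):
    """The two-fluid system cannot be solved (equal fluid densities)."""


class InconsistentMeasurementError(ValueError):
    """Two-fluid measurements imply a non-positive pellet volume."""


@dataclass(frozen=True)
class PelletState:
    """A pellet's intrinsic state: absolute mass (µg) and density (g/mL).

    Volume (nL) is derived, ``volume = absolute_mass / density``, so the
    identity ``volume * density == absolute_mass`` holds by construction.
    """

    absolute_mass: float
    density: float

    def __post_init__(self) -> None:
        if self.absolute_mass < 0:
            raise InvalidInputError("absolute_mass must be >= 0 µg")
        if self.density <= 0:
            raise InvalidInputError("pellet density must be > 0 g/mL")

    @property
    def volume(self) -> float:
        """Pellet volume in nL."""
        return self.absolute_mass / self.density


@dataclass(frozen=True)
class Fluid:
    """Carrier fluid: density (g/mL) and a free-text label."""

    density: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidInputError("fluid density must be > 0 g/mL")


@dataclass
class DensityCalibration:
    """Linear bulk-density model of the sensor.

    The resonance frequency falls linearly with fluid density over the
    calibrated span: ``f(rho) = reference_frequency + slope * (rho -
    reference_density)`` with ``slope`` in Hz per (g/mL), negative because
    a denser fluid adds mass to the tube.
    """

    slope: float
    reference_frequency: float
    reference_density: float
    valid_range: tuple[float, float] = (1.00, 1.08)
    r_squared: float | None = None
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError(
                "density slope must be negative (denser fluid lowers frequency)"
            )
        lo, hi = self.valid_range
        if not lo < hi:
            raise CalibrationError("valid_range must satisfy min < max")

    def to_dict(self) -> dict:
        return {
            "slope_hz_per_g_ml": self.slope,
            "reference_frequency_hz": self.reference_frequency,
            "reference_density_g_ml": self.reference_density,
            "valid_range_g_ml": list(self.valid_range),
            "r_squared": self.r_squared,
            "residual_sd_hz": self.residual_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityCalibration":
        return cls(
            slope=d["slope_hz_per_g_ml"],
            reference_frequency=d["reference_frequency_hz"],
            reference_density=d["reference_density_g_ml"],
            valid_range=tuple(d.get("valid_range_g_ml", (1.00, 1.08))),
            r_squared=d.get("r_squared"),
            residual_sd=d.get("residual_sd_hz"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DensityCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PointMassCalibration:
    """Point-mass model of the sensor.

    ``constant`` (K, g per Hz) converts a transit-peak height into buoyant
    mass; ``resolution`` (g) is the 1-sigma spread of replicate
    measurements of a constant reference bead, i.e. the smallest resolvable
    buoyant-mass difference.
    """

    constant: float
    resolution: float | None = None
    bead_buoyant_mass: float | None = None  # µg
    n_replicates: int = 0

    def __post_init__(self) -> None:
        if self.constant <= 0:
            raise CalibrationError("point-mass constant must be > 0 g/Hz")
        if self.resolution is not None and self.resolution <= 0:
            raise CalibrationError("resolution must be > 0 g")

    def to_dict(self) -> dict:
        return {
            "constant_g_per_hz": self.constant,
            "resolution_g": self.resolution,
            "bead_buoyant_mass_ug": self.bead_buoyant_mass,
            "n_replicates": self.n_replicates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PointMassCalibration":
        return cls(
            constant=d["constant_g_per_hz"],
            resolution=d.get("resolution_g"),
            bead_buoyant_mass=d.get("bead_buoyant_mass_ug"),
            n_replicates=int(d.get("n_replicates", 0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PointMassCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TwoFluidSolution:
    """Pellet properties recovered from buoyant masses in two fluids."""

    absolute_mass: float  # µg
    volume: float  # nL
    density: float  # g/mL


def buoyant_mass(pellet: PelletState, fluid: Fluid) -> float:
    """Signed buoyant mass (µg) of ``pellet`` immersed in ``fluid``.

    Positive when the pellet is denser than the fluid (it would sink and
    pulls the resonance frequency down during a transit), negative when it
    is lighter, zero when the densities match or the pellet is massless.
    """
    return pellet.absolute_mass * (1.0 - fluid.density / pellet.density)


def mass_to_shift(buoyant_mass_ug: float, cal: PointMassCalibration) -> float:
    """Peak height (Hz, signed) produced by a given buoyant mass (µg).

    Sign convention: positive buoyant mass (denser than fluid) gives a
    *downward* peak, i.e. a negative height relative to baseline.
    """
    return -buoyant_mass_ug * 1e-6 / cal.constant


def shift_to_mass(peak_height_hz: float, cal: PointMassCalibration) -> float:
    """Buoyant mass (µg, signed) from a transit-peak height (Hz, signed).

    Exact inverse of :func:`mass_to_shift`: downward peaks (negative
    height) map to positive buoyant mass.
    """
    return -peak_height_hz * cal.constant * 1e6


def density_from_frequency(frequency_hz: float, cal: DensityCalibration) -> float:
    """Fluid density (g/mL) from a bulk resonance frequency (Hz).

    Inverts the linear model; warns (does not fail) when the implied
    density falls outside the calibrated span, where the linear model is
    extrapolating.
    """
    if cal.slope == 0:
        raise CalibrationError("density calibration slope is zero")
    rho = cal.reference_density + (frequency_hz - cal.reference_frequency) / cal.slope
    lo, hi = cal.valid_range
    if not lo <= rho <= hi:
        warnings.warn(
            f"frequency {frequency_hz:.6g} Hz implies density {rho:.6g} g/mL, "
            f"outside the calibrated range [{lo}, {hi}] g/mL",
            stacklevel=2,
        )
    return rho


def frequency_from_density(density_g_ml: float, cal: DensityCalibration) -> float:
    """Bulk resonance frequency (Hz) at a given fluid density (g/mL)."""
    return cal.reference_frequency + cal.slope * (density_g_ml - cal.reference_density)


def solve_two_fluid(
    mb1: float, fluid1: Fluid, mb2: float, fluid2: Fluid
) -> TwoFluidSolution:
    """Recover absolute mass, volume and density from two buoyant masses.

    Given buoyant masses ``mb1``/``mb2`` (µg) of the *same* pellet measured
    in two fluids of different densities, solve the linear system
    ``m_b,i = V (rho_p - rho_f,i)``:

        V  = (mb1 - mb2) / (rho_f2 - rho_f1)        [nL]
        m  = mb1 + V * rho_f1                        [µg]
        rho_p = m / V                                [g/mL]

    Raises :class:`DegenerateSystemError` for equal fluid densities and
    :class:`InconsistentMeasurementError` when the implied volume is not
    positive (measurements cannot come from one physical pellet).
    """
    d1, d2 = fluid1.density, fluid2.density
    if d1 == d2:
        raise DegenerateSystemError("two-fluid solve requires distinct fluid densities")
    volume = (mb1 - mb2) / (d2 - d1)
    if volume <= 0:
        raise InconsistentMeasurementError(
            f"implied pellet volume {volume:.6g} nL is not positive"
        )
    mass = mb1 + volume * d1
    return TwoFluidSolution(absolute_mass=mass, volume=volume, density=mass / volume)
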