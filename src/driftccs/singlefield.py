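"""Single-field CCS determination.

At one fixed drift voltage, the drift time of an ion is linear in the
product γ·Ω of its CCS with a charge-and-mass factor

    γ = √(m1·mB / (m1 + mB)) / z          (√reduced-mass over charge)

so a set of calibrant ions with known CCS fixes the two instrument
parameters of

    td = β·γ·Ω + t_fix

(β the mobility-calibration slope, t_fix the transit time outside the
drift region), after which the relation is inverted for unknowns. The γ
factor is exactly the mass dependence of the Mason-Schamp equation, which
is what makes the single-field line consistent with the stepped-field
route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError, NonPhysicalValueError
from .physics import NITROGEN, DriftGas, IonSpecies, reduced_mass


@dataclass(frozen=True)
class CalibrantEntry:
    """One calibrant ion: identity, reference CCS (Å²) and its measured
    apex drift time (ms) at the fixed voltage."""

    ion: IonSpecies
    reference_ccs: float
    measured_drift_time: float

    def __post_init__(self) -> None:
        if self.reference_ccs <= 0:
            raise NonPhysicalValueError("reference CCS must be positive")
        if self.measured_drift_time <= 0:
            raise NonPhysicalValueError("drift time must be positive")


@dataclass(frozen=True)
class SingleFieldCalibration:
    """Fitted single-field calibration: slope β (ms per γ·Å²), intercept
    t_fix (ms), the fixed drift voltage, and the calibration r²."""

    beta: float
    t_fix: float
    fixed_voltage: float = 1700.0
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise DegenerateFitError(f"beta must be positive, got {self.beta}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "beta": self.beta,
            "t_fix": self.t_fix,
            "fixed_voltage_v": self.fixed_voltage,
            "r_squared": self.r_squared,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SingleFieldCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            beta=d["beta"],
            t_fix=d["t_fix"],
            fixed_voltage=d.get("fixed_voltage_v", 1700.0),
            r_squared=d.get("r_squared", float("nan")),
        )


def gamma(ion: IonSpecies, gas: DriftGas = NITROGEN) -> float:
    """Charge-and-mass factor γ = √(reduced mass)/z (Da^½).

    Strictly increasing in the ion mass at fixed gas mass; halves when
    the charge count doubles.
    """
    return np.sqrt(reduced_mass(gas.molar_mass, ion.mass)) / ion.z


def fit_single_field(
    calibrants: list[CalibrantEntry] | tuple[CalibrantEntry, ...],
    gas: DriftGas = NITROGEN,
    fixed_voltage: float = 1700.0,
) -> SingleFieldCalibration:
    """Least-squares fit of measured drift time against γ·Ω over the
    calibrant set; the slope is β and the intercept t_fix."""
    if len(calibrants) < 2:
        raise InsufficientDataError(
            f"single-field calibration needs >= 2 calibrants, got {len(calibrants)}"
        )
    x = np.array([gamma(c.ion, gas) * c.reference_ccs for c in calibrants])
    y = np.array([c.measured_drift_time for c in calibrants])
    if np.ptp(x) == 0:
        raise InsufficientDataError(
            "calibrants have identical gamma*CCS products; the design is rank deficient"
        )
    res = stats.linregress(x, y)
    r_squared = float(res.rvalue**2) if len(calibrants) > 2 else 1.0
    if res.slope <= 0:
        raise DegenerateFitError(
            "non-positive calibration slope: drift times do not increase with gamma*CCS"
        )
    return SingleFieldCalibration(
        beta=float(res.slope),
        t_fix=float(res.intercept),
        fixed_voltage=fixed_voltage,
        r_squared=r_squared,
    )


def ccs_single_field(
    td: float,
    ion: IonSpecies,
    cal: SingleFieldCalibration,
    gas: DriftGas = NITROGEN,
) -> float:
    """Invert the calibration: Ω = (td − t_fix) / (β·γ), in Å²."""
    if td <= cal.t_fix:
        raise NonPhysicalValueError(
            f"drift time {td} ms does not exceed the fixed transit time "
            f"{cal.t_fix} ms; no time was spent in the drift region"
        )
    return (td - cal.t_fix) / (cal.beta * gamma(ion, gas))


def single_multi_agreement(ccs_single: float, ccs_multi: float) -> float:
    """Agreement between the two CCS routes, in percent.

    The population standard deviation of the pair over its mean,
    ``100·(|a − b|/2)/((a + b)/2)`` — i.e. half the relative spread.
    Symmetric and scale invariant.
    """
    if ccs_single <= 0 or ccs_multi <= 0:
        raise NonPhysicalValueError("CCS values must be positive")
    return 100.0 * abs(ccs_single - ccs_multi) / (ccs_single + ccs_multi)
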