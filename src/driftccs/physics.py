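"""Drift-tube ion-mobility physics.

Kinetic-theory relations shared by both CCS determination routes:

* the Mason-Schamp equation linking the reduced mobility ``K0`` of an ion
  to its momentum-transfer collision cross section (CCS, symbol Ω) with a
  buffer gas,

  .. math::

      \\Omega = \\frac{3 z e}{16 N_0}
                \\sqrt{\\frac{2\\pi}{\\mu k_B T}} \\; \\frac{1}{K_0}

  where ``μ = m1·mB/(m1 + mB)`` is the ion/gas reduced mass, ``z`` the
  charge count, ``N0`` the buffer-gas number density at standard
  conditions (1 atm, 273.15 K) and ``T`` the drift-gas temperature;

* drift-tube kinematics: an ion with reduced mobility ``K0`` in a tube of
  length ``L`` under drift voltage ``V`` arrives at

  .. math::

      t_d = t_0 + \\frac{L^2}{K V},
      \\qquad K = K_0 \\frac{760}{P[\\mathrm{torr}]} \\frac{T}{273.15}

  with ``t0`` the voltage-independent transit time spent outside the
  drift region.

Units follow drift-tube conventions: CCS in Å², reduced mobility in
cm²/(V·s), drift time in ms, tube length in m, pressure in torr.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import NonPhysicalValueError

# CODATA 2018 exact values.
BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
DALTON_KG = 1.66053906660e-27

ATM_PA = 101325.0
TORR_PA = ATM_PA / 760.0
STANDARD_TEMPERATURE_K = 273.15

#: Buffer-gas number density at 1 atm and 273.15 K (Loschmidt constant),
#: ≈ 2.687e25 m⁻³.
LOSCHMIDT_PER_M3 = ATM_PA / (BOLTZMANN_J_PER_K * STANDARD_TEMPERATURE_K)

NITROGEN_MOLAR_MASS_DA = 28.0134


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise NonPhysicalValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class DriftGas:
    """Identity and molar mass (Da) of the drift/buffer gas."""

    name: str = "nitrogen"
    molar_mass: float = NITROGEN_MOLAR_MASS_DA

    def __post_init__(self) -> None:
        _require_positive(molar_mass=self.molar_mass)


NITROGEN = DriftGas()


@dataclass(frozen=True)
class IonSpecies:
    """A measured ion: label, mass-to-charge (Th) and charge count.

    For the singly protonated species that dominate small-molecule work,
    ``mz`` is numerically the ion mass in Da; for ``z > 1`` the ion mass
    is ``mz * z``.
    """

    name: str
    mz: float
    z: int = 1

    def __post_init__(self) -> None:
        _require_positive(mz=self.mz)
        if self.z < 1:
            raise NonPhysicalValueError(f"charge count must be >= 1, got {self.z}")

    @property
    def mass(self) -> float:
        """Ion mass in Da (``mz * z``)."""
        return self.mz * self.z


@dataclass(frozen=True)
class InstrumentConfig:
    """Drift-tube geometry and drift-gas state.

    Defaults reflect a commercial uniform-field drift tube: 78.1 cm tube,
    nitrogen near 4 torr, and an effective in-tube gas temperature of
    300 K. The temperature that enters the Mason-Schamp equation is the
    gas temperature inside the drift region, which is not the source-gas
    setpoint; it is therefore left as a free, overridable parameter.
    """

    tube_length: float = 0.781       # m
    drift_pressure: float = 3.95     # torr
    drift_temperature: float = 300.0  # K
    gas: DriftGas = field(default_factory=lambda: NITROGEN)

    def __post_init__(self) -> None:
        _require_positive(
            tube_length=self.tube_length,
            drift_pressure=self.drift_pressure,
            drift_temperature=self.drift_temperature,
        )

    @property
    def pressure_pa(self) -> float:
        return self.drift_pressure * TORR_PA

    @property
    def number_density(self) -> float:
        """Drift-gas number density at operating P, T (m⁻³)."""
        return gas_number_density(self.pressure_pa, self.drift_temperature)

    # -- JSON round trip with unit-bearing keys ---------------------------

    def to_dict(self) -> dict:
        return {
            "tube_length_m": self.tube_length,
            "drift_pressure_torr": self.drift_pressure,
            "drift_temperature_k": self.drift_temperature,
            "gas_name": self.gas.name,
            "gas_molar_mass_da": self.gas.molar_mass,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        return cls(
            tube_length=d.get("tube_length_m", 0.781),
            drift_pressure=d.get("drift_pressure_torr", 3.95),
            drift_temperature=d.get("drift_temperature_k", 300.0),
            gas=DriftGas(
                name=d.get("gas_name", "nitrogen"),
                molar_mass=d.get("gas_molar_mass_da", NITROGEN_MOLAR_MASS_DA),
            ),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InstrumentConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def reduced_mass(m1: float, mb: float) -> float:
    """Reduced mass ``m1·mB / (m1 + mB)`` of the gas/ion pair, in Da.

    Symmetric in its arguments; raises for non-positive masses.
    """
    _require_positive(m1=m1, mb=mb)
    return m1 * mb / (m1 + mb)


def gas_number_density(pressure_pa: float, temperature_k: float) -> float:
    """Ideal-gas number density ``P / (kB·T)`` in m⁻³."""
    _require_positive(pressure_pa=pressure_pa, temperature_k=temperature_k)
    return pressure_pa / (BOLTZMANN_J_PER_K * temperature_k)


def _mason_schamp_constant(ion: IonSpecies, gas: DriftGas, temperature_k: float) -> float:
    """The product Ω·K0 (m² · m²/(V·s)) fixed by kinetic theory.

    Mason-Schamp ties CCS and reduced mobility together through
    ``Ω·K0 = (3 z e / 16 N0) · sqrt(2π / (μ kB T))``; either quantity
    follows from the other by division.
    """
    mu_kg = reduced_mass(gas.molar_mass, ion.mass) * DALTON_KG
    return (
        3.0 * ion.z * ELEMENTARY_CHARGE_C
        / (16.0 * LOSCHMIDT_PER_M3)
        * math.sqrt(2.0 * math.pi / (mu_kg * BOLTZMANN_J_PER_K * temperature_k))
    )


def ccs_from_k0(
    k0: float,
    ion: IonSpecies,
    gas: DriftGas = NITROGEN,
    temperature_k: float = 300.0,
) -> float:
    """Collision cross section (Å²) from reduced mobility (cm²/(V·s)).

    Strictly decreasing in both ``k0`` and ``temperature_k``.
    """
    _require_positive(k0=k0, temperature_k=temperature_k)
    k0_si = k0 * 1e-4  # cm²/(V·s) -> m²/(V·s)
    omega_m2 = _mason_schamp_constant(ion, gas, temperature_k) / k0_si
    return omega_m2 * 1e20  # m² -> Å²


def k0_from_ccs(
    ccs: float,
    ion: IonSpecies,
    gas: DriftGas = NITROGEN,
    temperature_k: float = 300.0,
) -> float:
    """Reduced mobility (cm²/(V·s)) from CCS (Å²): exact inverse of
    :func:`ccs_from_k0`."""
    _require_positive(ccs=ccs, temperature_k=temperature_k)
    omega_m2 = ccs * 1e-20
    k0_si = _mason_schamp_constant(ion, gas, temperature_k) / omega_m2
    return k0_si * 1e4


def mobility_at_operating_conditions(k0: float, cfg: InstrumentConfig) -> float:
    """Actual mobility K (m²/(V·s)) at the instrument's P, T from the
    reduced mobility K0 (cm²/(V·s))."""
    _require_positive(k0=k0)
    return (
        k0
        * 1e-4
        * (760.0 / cfg.drift_pressure)
        * (cfg.drift_temperature / STANDARD_TEMPERATURE_K)
    )


def drift_time(
    k0: float,
    voltage: float,
    cfg: InstrumentConfig,
    t0_ms: float = 0.0,
) -> float:
    """Arrival time (ms) of an ion of reduced mobility ``k0`` at drift
    voltage ``voltage``: ``t0 + L² / (K·V)``.

    Strictly decreasing in voltage and in mobility; ``t0`` is the
    voltage-independent transit time outside the drift region.
    """
    _require_positive(k0=k0, voltage=voltage)
    k = mobility_at_operating_conditions(k0, cfg)
    return t0_ms + 1e3 * cfg.tube_length**2 / (k * voltage)
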