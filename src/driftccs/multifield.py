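"""Stepped-field (multi-field) CCS determination.

Drift times measured at a ladder of drift voltages are regressed against
1/V. The slope isolates the mobility (``td - t0 = L²/(K·V)``) and the
intercept the voltage-independent transit time ``t0``, so the method
yields the reduced mobility K0 — and through Mason-Schamp the CCS —
without any calibrant ions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError
from .physics import (
    STANDARD_TEMPERATURE_K,
    InstrumentConfig,
    IonSpecies,
    ccs_from_k0,
)

#: Stepped-field fits on a uniform drift tube are expected to be almost
#: perfectly linear; anything below this r² is flagged in reports.
R_SQUARED_WARN_THRESHOLD = 0.999


@dataclass(frozen=True)
class SteppedFieldSeries:
    """Apex drift times for one ion across a drift-voltage ladder.

    ``points`` is a sequence of ``(drift_voltage_V, apex_drift_time_ms)``
    pairs with strictly increasing voltages. Drift time should decrease
    with voltage; a violation is physically suspect and triggers a
    warning, not an error, so that noisy-but-recoverable data still fits.
    """

    ion: IonSpecies
    points: tuple[tuple[float, float], ...]
    cfg: InstrumentConfig = field(default_factory=InstrumentConfig)

    def __post_init__(self) -> None:
        pts = tuple((float(v), float(t)) for v, t in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise InsufficientDataError(
                f"stepped-field series needs >= 3 voltages, got {len(pts)}"
            )
        voltages = [v for v, _ in pts]
        times = [t for _, t in pts]
        if any(b <= a for a, b in zip(voltages, voltages[1:])):
            raise DegenerateFitError(
                "drift voltages must be strictly increasing and distinct"
            )
        if any(t <= 0 for t in times):
            raise DegenerateFitError("drift times must be positive")
        if any(b >= a for a, b in zip(times, times[1:])):
            warnings.warn(
                f"{self.ion.name}: drift time does not decrease monotonically "
                "with voltage; check peak assignments",
                stacklevel=2,
            )

    @property
    def voltages(self) -> np.ndarray:
        return np.array([v for v, _ in self.points])

    @property
    def drift_times(self) -> np.ndarray:
        return np.array([t for _, t in self.points])


@dataclass(frozen=True)
class MobilityFit:
    """Result of the stepped-field regression: reduced mobility K0
    (cm²/(V·s)), transit-time intercept t0 (ms), r² and per-point
    residuals (ms)."""

    k0: float
    t0: float
    r_squared: float
    residuals: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise DegenerateFitError(f"fitted k0 must be positive, got {self.k0}")


def fit_stepped_field(series: SteppedFieldSeries, robust: bool = False) -> MobilityFit:
    """Regress drift time on inverse drift voltage and convert the slope
    to a reduced mobility.

    The slope ``s`` (ms·V) equals ``1000·L²/K`` with K the mobility at
    operating pressure and temperature; K0 follows by normalising to
    760 torr and 273.15 K. ``robust=True`` swaps ordinary least squares
    for a Theil-Sen median-of-slopes fit (outlier tolerant; r² is still
    reported from the OLS residuals around the robust line).
    """
    x = 1.0 / series.voltages
    y = series.drift_times
    if robust:
        slope, intercept, _, _ = stats.theilslopes(y, x)
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
    predicted = intercept + slope * x
    ss_res = float(np.sum((y - predicted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope <= 0:
        raise DegenerateFitError(
            "non-positive drift-time/inverse-voltage slope: drift times do "
            "not increase as voltage drops (mis-ordered or mis-labelled input?)"
        )
    cfg = series.cfg
    k = 1e3 * cfg.tube_length**2 / slope  # m²/(V·s) at operating P, T
    k0 = (
        k
        * 1e4
        * (cfg.drift_pressure / 760.0)
        * (STANDARD_TEMPERATURE_K / cfg.drift_temperature)
    )
    return MobilityFit(
        k0=k0,
        t0=float(intercept),
        r_squared=min(max(r_squared, 0.0), 1.0),
        residuals=tuple(float(r) for r in (y - predicted)),
    )


def ccs_multifield(fit: MobilityFit, ion: IonSpecies, cfg: InstrumentConfig) -> float:
    """CCS (Å²) from a stepped-field mobility fit, via Mason-Schamp at
    the instrument's drift-gas temperature."""
    return ccs_from_k0(fit.k0, ion, cfg.gas, cfg.drift_temperature)
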