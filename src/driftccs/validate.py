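"""Quantitative method-validation calculus.

Everything needed to turn calibration-series and sample peak areas into
the usual validation report for a small-molecule assay: calibration
linearity with 95% confidence intervals on slope and intercept,
signal-to-noise based LOD/LOQ (with the residual-based ICH route as an
alternative), replicate precision as %RSD, spike recovery, matrix
effect, and conversion of an extract concentration into per-gram sample
content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError, NonPhysicalValueError

#: Calibration r² below which linearity is flagged in reports.
R_SQUARED_ACCEPT = 0.991

LOD_SNR_FACTOR = 3.3
LOQ_SNR_FACTOR = 10.0


@dataclass(frozen=True)
class CalibrationSeries:
    """Calibration data for one analyte: concentration levels (µg/mL),
    each with a list of replicate peak areas."""

    analyte: str
    levels: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        lv = tuple(
            (float(c), tuple(float(a) for a in areas)) for c, areas in self.levels
        )
        object.__setattr__(self, "levels", lv)
        concs = [c for c, _ in lv]
        if len(set(concs)) < 3:
            raise InsufficientDataError(
                f"{self.analyte}: calibration needs >= 3 distinct concentrations"
            )
        if any(c <= 0 for c in concs):
            raise NonPhysicalValueError("concentrations must be positive")
        if any(len(a) == 0 for _, a in lv):
            raise InsufficientDataError("every level needs at least one replicate area")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.levels])

    @property
    def mean_areas(self) -> np.ndarray:
        return np.array([float(np.mean(a)) for _, a in self.levels])


@dataclass(frozen=True)
class LinearityResult:
    """Calibration-line fit with two-sided confidence intervals.

    ``slope_ci`` / ``intercept_ci`` are half-widths of the t-based CI at
    the requested confidence (n − 2 degrees of freedom over the level
    means). ``residual_sd`` feeds the ICH-style LOD/LOQ route.
    """

    slope: float
    slope_ci: float
    intercept: float
    intercept_ci: float
    r_squared: float
    range_ug_ml: tuple[float, float]
    residual_sd: float = 0.0
    confidence: float = 0.95

    @property
    def acceptable(self) -> bool:
        return self.r_squared >= R_SQUARED_ACCEPT

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def invert(self, area: float) -> float:
        """Concentration back-calculated from a peak area."""
        return (area - self.intercept) / self.slope


def fit_linearity(
    series: CalibrationSeries,
    confidence: float = 0.95,
    weighting: str | None = None,
) -> LinearityResult:
    """Fit the calibration line of mean peak area against concentration.

    Unweighted OLS by default. ``weighting="1/x2"`` applies inverse
    concentration-squared weights, which equalises relative errors when
    the range spans orders of magnitude. Confidence intervals come from
    the t distribution with ``n_levels − 2`` degrees of freedom.
    """
    x = series.concentrations
    y = series.mean_areas
    n = x.size
    if np.ptp(x) == 0:
        raise DegenerateFitError("all concentrations identical; cannot fit a line")
    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "1/x2":
        w = 1.0 / x**2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    dof = n - 2
    ss_res = np.sum(w * resid**2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r_squared = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
    if dof > 0:
        s2 = ss_res / dof
        se_slope = np.sqrt(s2 / sxx)
        se_intercept = np.sqrt(s2 * (1.0 / sw + xbar**2 / sxx))
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
        residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    else:
        se_slope = se_intercept = residual_sd = 0.0
        tcrit = 0.0
    return LinearityResult(
        slope=float(slope),
        slope_ci=float(tcrit * se_slope),
        intercept=float(intercept),
        intercept_ci=float(tcrit * se_intercept),
        r_squared=min(max(r_squared, 0.0), 1.0),
        range_ug_ml=(float(x.min()), float(x.max())),
        residual_sd=residual_sd,
        confidence=confidence,
    )


def lod(concentration: float, snr: float) -> float:
    """Limit of detection from a reference concentration and its measured
    signal-to-noise ratio: ``3.3 · c / m``. Same units as ``c``."""
    if concentration <= 0:
        raise NonPhysicalValueError("concentration must be positive")
    if snr <= 0:
        raise NonPhysicalValueError("signal-to-noise ratio must be positive")
    return LOD_SNR_FACTOR * concentration / snr


def loq(concentration: float, snr: float) -> float:
    """Limit of quantification: ``10 · c / m``. Always ≥ the LOD from the
    same inputs (10 > 3.3)."""
    if concentration <= 0:
        raise NonPhysicalValueError("concentration must be positive")
    if snr <= 0:
        raise NonPhysicalValueError("signal-to-noise ratio must be positive")
    return LOQ_SNR_FACTOR * concentration / snr


def lod_from_fit(fit: LinearityResult) -> float:
    """ICH-style LOD, ``3.3 · s_resid / slope`` — the alternative when no
    per-analyte S/N measurement exists."""
    if fit.slope <= 0:
        raise NonPhysicalValueError("calibration slope must be positive")
    return LOD_SNR_FACTOR * fit.residual_sd / fit.slope


def loq_from_fit(fit: LinearityResult) -> float:
    """ICH-style LOQ, ``10 · s_resid / slope``."""
    if fit.slope <= 0:
        raise NonPhysicalValueError("calibration slope must be positive")
    return LOQ_SNR_FACTOR * fit.residual_sd / fit.slope


def precision_rsd(values) -> float:
    """Relative standard deviation of replicates, percent
    (sample SD, n − 1 divisor, over the mean)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("precision needs >= 2 replicates")
    mean = v.mean()
    if mean == 0:
        raise NonPhysicalValueError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))


def recovery(measured_total: float, base: float, added: float) -> float:
    """Spike recovery, percent: ``100 · (measured_total − base) / added``."""
    if added <= 0:
        raise NonPhysicalValueError("added amount must be positive")
    return 100.0 * (measured_total - base) / added


def matrix_effect(area_matrix: float, area_solvent: float) -> float:
    """Matrix effect, percent: analyte response in matrix over response
    in pure solvent, ×100. 100% means no suppression or enhancement."""
    if area_solvent <= 0:
        raise NonPhysicalValueError("solvent-standard area must be positive")
    return 100.0 * area_matrix / area_solvent


def sample_content(
    conc_ug_ml: float,
    elution_volume_ml: float = 0.2,
    sample_mass_mg: float = 30.0,
) -> float:
    """Per-gram content of the original sample from the extract
    concentration: ``c · V / m · 1000``.

    With the default micro-extraction geometry (30 mg sample eluted in
    200 µL) the factor is ×20/3 ≈ 6.667. Dimensionally the result is
    µg of analyte per g of sample; assay reports conventionally print it
    on a "mg/g" scale, which this function reproduces.
    """
    if conc_ug_ml < 0:
        raise NonPhysicalValueError("concentration cannot be negative")
    if elution_volume_ml <= 0 or sample_mass_mg <= 0:
        raise NonPhysicalValueError("volume and mass must be positive")
    return conc_ug_ml * elution_volume_ml / sample_mass_mg * 1000.0


@dataclass(frozen=True)
class ValidationReport:
    """Per-analyte validation summary."""

    analyte: str
    linearity: LinearityResult
    lod_ng_ml: float | None = None
    loq_ng_ml: float | None = None
    intra_day_rsd_pct: float | None = None
    inter_day_rsd_pct: float | None = None
    recovery_pct: dict = field(default_factory=dict)  # spike level -> %
    recovery_mode: str = "mean"  # "mean" over replicates or "single"
    matrix_effect_pct: float | None = None
    content_ug_ml: float | None = None
    content_per_g: float | None = None

    def __post_init__(self) -> None:
        if (
            self.lod_ng_ml is not None
            and self.loq_ng_ml is not None
            and self.lod_ng_ml > self.loq_ng_ml
        ):
            raise NonPhysicalValueError("LOD cannot exceed LOQ")

    def to_dict(self) -> dict:
        lin = self.linearity
        return {
            "analyte": self.analyte,
            "slope": lin.slope,
            "slope_ci95": lin.slope_ci,
            "intercept": lin.intercept,
            "intercept_ci95": lin.intercept_ci,
            "r_squared": lin.r_squared,
            "linear_range_ug_ml": list(lin.range_ug_ml),
            "linearity_acceptable": lin.acceptable,
            "lod_ng_ml": self.lod_ng_ml,
            "loq_ng_ml": self.loq_ng_ml,
            "intra_day_rsd_pct": self.intra_day_rsd_pct,
            "inter_day_rsd_pct": self.inter_day_rsd_pct,
            "recovery_pct": {str(k): v for k, v in self.recovery_pct.items()},
            "recovery_mode": self.recovery_mode,
            "matrix_effect_pct": self.matrix_effect_pct,
            "content_ug_ml": self.content_ug_ml,
            "content_per_g": self.content_per_g,
        }
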