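"""Arrival-time-distribution peak picking.

Drift peaks from a uniform-field tube are very nearly Gaussian, so the
apex of a picked local maximum is refined by fitting a parabola through
the log-intensities of the three samples around it — exact for a
Gaussian, free of iterative-fit failures, and accurate to a small
fraction of the grid spacing. Noise is estimated from the first and last
deciles of the trace (drift peaks sit mid-trace), as the median absolute
deviation scaled to a Gaussian sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt, pi

import numpy as np
from scipy.signal import find_peaks

from .errors import NonPhysicalValueError

_MAD_TO_SIGMA = 1.4826
_FWHM_PER_SIGMA = 2.0 * sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class DriftSpectrum:
    """One arrival-time distribution: a uniform time grid (ms) with
    non-negative intensities, optionally tagged with the compound and
    the drift voltage it was recorded at."""

    times: np.ndarray
    intensities: np.ndarray
    compound: str | None = None
    drift_voltage: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.shape != y.shape or t.ndim != 1:
            raise NonPhysicalValueError("times and intensities must be equal-length 1-D arrays")
        if t.size < 16:
            raise NonPhysicalValueError(f"spectrum needs >= 16 samples, got {t.size}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise NonPhysicalValueError("time axis must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise NonPhysicalValueError("time axis must be uniformly spaced")
        if np.any(y < 0):
            raise NonPhysicalValueError("intensities must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class PickedPeak:
    """A picked drift peak: refined apex time (ms), height (counts),
    Gaussian-equivalent FWHM (ms) and area (counts·ms)."""

    apex_time: float
    height: float
    fwhm: float
    area: float


def _tails(spec: DriftSpectrum) -> np.ndarray:
    n = spec.intensities.size
    k = max(1, n // 10)
    return np.concatenate([spec.intensities[:k], spec.intensities[-k:]])


def baseline_level(spec: DriftSpectrum) -> float:
    """Detector baseline: median of the outer deciles of the trace."""
    return float(np.median(_tails(spec)))


def noise_scale(spec: DriftSpectrum) -> float:
    """Robust noise sigma from the outer deciles of the trace."""
    tails = _tails(spec)
    mad = np.median(np.abs(tails - np.median(tails)))
    return float(_MAD_TO_SIGMA * mad)


def _refine_apex(spec: DriftSpectrum, i: int, y: np.ndarray) -> PickedPeak:
    """Three-point parabolic refinement around sample ``i`` of the
    baseline-subtracted trace ``y``.

    Uses log-intensities when all three samples are positive (exact for a
    Gaussian peak); falls back to a plain parabola otherwise. Degenerate
    (flat-top) neighbourhoods keep the grid apex and a one-bin width.
    """
    t, dt = spec.times, spec.dt
    left, centre, right = y[i - 1], y[i], y[i + 1]
    use_log = min(left, centre, right) > 0
    if use_log:
        l, c, r = np.log(left), np.log(centre), np.log(right)
    else:
        l, c, r = left, centre, right
    denom = 2.0 * c - l - r  # >= 0 since centre is a local max
    if denom > 0:
        p = 0.5 * (l - r) / (-denom)  # sub-bin offset in [-0.5, 0.5]
        p = float(np.clip(p, -0.5, 0.5))
        apex_val = c - 0.25 * (l - r) * p
    else:
        p, apex_val = 0.0, c
    apex_time = float(t[i] + p * dt)
    if use_log:
        height = float(np.exp(apex_val))
        sigma = dt / sqrt(denom) if denom > 0 else dt
    else:
        height = float(apex_val)
        # parabola curvature -> Gaussian sigma via matching second derivative
        sigma = dt * sqrt(height / denom) if denom > 0 and height > 0 else dt
    return PickedPeak(
        apex_time=apex_time,
        height=height,
        fwhm=float(_FWHM_PER_SIGMA * sigma),
        area=float(height * sigma * sqrt(2.0 * pi)),
    )


def pick_peaks(
    spec: DriftSpectrum,
    min_snr: float = 5.0,
    max_peaks: int = 10,
) -> list[PickedPeak]:
    """Locate up to ``max_peaks`` local maxima above ``min_snr`` times
    the robust noise scale, refine each apex, and return them sorted by
    descending height (ties broken by earlier apex).

    Heights and the S/N threshold are measured above the detector
    baseline (median of the trace's outer deciles). A flat or empty
    trace yields an empty list, not an error; a noiseless trace degrades
    the threshold to "any local maximum strictly above baseline".
    """
    if np.ptp(spec.intensities) == 0:
        return []
    y = spec.intensities - baseline_level(spec)
    sigma = noise_scale(spec)
    threshold = min_snr * sigma if sigma > 0 else np.finfo(float).tiny
    idx, _ = find_peaks(y, height=threshold)
    peaks = [_refine_apex(spec, i, y) for i in idx]
    peaks.sort(key=lambda p: (-p.height, p.apex_time))
    return peaks[:max_peaks]


def estimate_snr(spec: DriftSpectrum, peak: PickedPeak) -> float:
    """Signal-to-noise ratio of a picked peak: its height over the
    robust noise scale of the trace it came from.

    A noiseless trace has no finite S/N; an infinity sentinel is returned
    with a warning.
    """
    if not (spec.times[0] <= peak.apex_time <= spec.times[-1]):
        raise NonPhysicalValueError("peak apex lies outside the spectrum time range")
    sigma = noise_scale(spec)
    if sigma == 0:
        warnings.warn("zero noise estimate; returning infinite S/N", stacklevel=2)
        return float("inf")
    return peak.height / sigma
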