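"""Multifractal detrended fluctuation analysis (MFDFA).

Turbulent exhalation records are multifractal: the scaling exponent of the
fluctuation function depends on the moment order q. MFDFA estimates this by

1. integrating the mean-subtracted series into a profile,
2. splitting the profile at each scale ``s`` into ``floor(N/s)`` windows
   from both ends (``2*floor(N/s)`` in total, so no tail is wasted),
3. removing a polynomial trend of order ``detrend_order`` from each window
   and recording the residual variance F²(v, s),
4. averaging the q/2-th moments of F² into the fluctuation function
   F_q(s) (a log-average at q = 0).

The generalized Hurst exponent h(q) is the log–log slope of F_q(s); the
mass exponent is τ(q) = q·h(q) − 1 and the singularity spectrum follows by
Legendre transform, α = dτ/dq, f(α) = q·α − τ(q).

Three scalars summarize a spectrum and are the multifractal part of the
biometric signature: β (the singularity strength at the spectral maximum),
ω = α_max − α_min (spectrum width, the degree of multifractality), and
ε ∈ [−1, 1] (normalized asymmetry of the two spectrum branches). Segments
whose spectrum is non-convex (folded) or narrower than ``width_min`` are
rejected; MFDFA thus doubles as a segment-quality filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "FluctuationSurface",
    "MultifractalSpectrum",
    "SpectrumFeatures",
    "SegmentValidity",
    "ValidityReason",
    "DegenerateSeriesError",
    "default_q_grid",
    "default_scales",
    "mfdfa_fluctuations",
    "singularity_spectrum",
    "spectrum_features",
    "check_validity",
    "analyze_segment",
]


class DegenerateSeriesError(ValueError):
    """Raised when every detrended window has zero variance."""


class ValidityReason(str, Enum):
    OK = "ok"
    NON_CONVEX = "non_convex"
    WIDTH_BELOW_MIN = "width_below_min"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class SegmentValidity:
    valid: bool
    reason: ValidityReason

    def __post_init__(self) -> None:
        if self.valid != (self.reason is ValidityReason.OK):
            raise ValueError("valid flag inconsistent with reason")


@dataclass(frozen=True)
class FluctuationSurface:
    """F_q(s) on a (q, scale) grid, all entries finite and positive."""

    scales: np.ndarray
    q_grid: np.ndarray
    Fq: np.ndarray  # shape (len(q_grid), len(scales))


@dataclass(frozen=True)
class MultifractalSpectrum:
    alpha: np.ndarray
    f_alpha: np.ndarray
    hq: np.ndarray
    tau_q: np.ndarray
    q_grid: np.ndarray


@dataclass(frozen=True)
class SpectrumFeatures:
    beta: float
    omega: float
    epsilon: float


def default_q_grid(q_min: float = -5.0, q_max: float = 5.0,
                   q_step: float = 0.25) -> np.ndarray:
    """Moment orders −5..5 in steps of 0.25; q = 0 is handled specially."""
    n = int(round((q_max - q_min) / q_step)) + 1
    return np.linspace(q_min, q_max, n)


def default_scales(n_samples: int, scale_min: int = 16,
                   n_scales: int = 10) -> np.ndarray:
    """Log-spaced integer scales in [scale_min, N/4].

    The lower bound avoids polynomial-detrending artifacts in very short
    windows; the upper bound is the usual N/4 rule keeping at least four
    windows per end.
    """
    scale_max = n_samples // 4
    if scale_max <= scale_min:
        raise ValueError(
            f"series of {n_samples} samples too short for scale_min={scale_min}")
    scales = np.unique(np.geomspace(scale_min, scale_max, n_scales)
                       .round().astype(int))
    return scales


def mfdfa_fluctuations(series: np.ndarray,
                       scales: np.ndarray | None = None,
                       q_grid: np.ndarray | None = None,
                       detrend_order: int = 1) -> FluctuationSurface:
    """Compute the fluctuation surface F_q(s) of one series."""
    x = np.asarray(series, dtype=float)
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if scales is None:
        scales = default_scales(x.size)
    scales = np.asarray(scales, dtype=int)
    if detrend_order < 1:
        raise ValueError("detrend_order must be >= 1")
    if x.size < 4 * scales.min():
        raise ValueError("series shorter than 4 times the smallest scale")

    profile = np.cumsum(x - x.mean())
    n = profile.size
    t_cache = {int(s): np.arange(int(s), dtype=float) for s in scales}

    Fq = np.empty((q_grid.size, scales.size))
    for si, s in enumerate(scales):
        s = int(s)
        ns = n // s
        # windows from the start and from the end so the tail is covered
        windows = np.concatenate(
            [profile[:ns * s].reshape(ns, s),
             profile[n - ns * s:].reshape(ns, s)], axis=0)
        t = t_cache[s]
        coef = np.polynomial.polynomial.polyfit(t, windows.T, detrend_order)
        resid = windows - np.polynomial.polynomial.polyval(t, coef)
        f2 = np.mean(resid ** 2, axis=1)
        f2 = f2[f2 > 0]
        if f2.size == 0:
            raise DegenerateSeriesError(
                "all detrended windows have zero variance")
        logf2 = np.log(f2)
        for qi, q in enumerate(q_grid):
            if q == 0.0:
                Fq[qi, si] = np.exp(0.5 * logf2.mean())
            else:
                # moments computed in log space for numerical range safety
                m = np.exp((q / 2.0) * logf2)
                Fq[qi, si] = m.mean() ** (1.0 / q)
    return FluctuationSurface(scales, q_grid, Fq)


def singularity_spectrum(surface: FluctuationSurface) -> MultifractalSpectrum:
    """Legendre-transform the fluctuation surface into f(α).

    h(q) is the least-squares slope of log F_q against log s; α is the
    derivative of τ(q) = q·h(q) − 1 by central finite differences
    (one-sided at the ends of the q grid).
    """
    if surface.scales.size < 3:
        raise ValueError("need at least 3 scales for the log-log regression")
    logs = np.log(surface.scales.astype(float))
    logF = np.log(surface.Fq)
    # vectorized least-squares slope per q row
    xc = logs - logs.mean()
    hq = (logF - logF.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    q = surface.q_grid
    tau = q * hq - 1.0
    alpha = np.gradient(tau, q)
    f_alpha = q * alpha - tau
    return MultifractalSpectrum(alpha, f_alpha, hq, tau, q)


def spectrum_features(spectrum: MultifractalSpectrum) -> SpectrumFeatures:
    """Extract (β, ω, ε) from a singularity spectrum.

    β is the singularity strength at the spectrum maximum, ω the width
    α_max − α_min, and ε the normalized branch-width difference
    ((α_max − β) − (β − α_min)) / ω — zero for a symmetric spectrum,
    positive when the right (weak-singularity) branch dominates.
    """
    alpha = spectrum.alpha
    f = spectrum.f_alpha
    beta = float(alpha[np.argmax(f)])
    a_min, a_max = float(alpha.min()), float(alpha.max())
    omega = a_max - a_min
    if omega == 0.0:
        return SpectrumFeatures(beta, 0.0, 0.0)
    epsilon = ((a_max - beta) - (beta - a_min)) / omega
    return SpectrumFeatures(beta, float(omega), float(epsilon))


def check_validity(spectrum: MultifractalSpectrum, width_min: float = 0.05,
                   convexity_tol: float = 0.01) -> SegmentValidity:
    """Classify a spectrum as usable or not.

    A well-behaved multifractal spectrum is an inverted parabola: as q
    decreases over its grid, α increases monotonically and f(α) rises to a
    single maximum and falls. A fold (α reversing direction) or a
    multi-modal f(α) marks a non-convex spectrum; a width below
    ``width_min`` marks a segment with too little multifractality to be a
    reliable signature. Tolerance absorbs finite-difference jitter.
    """
    alpha = spectrum.alpha
    f = spectrum.f_alpha
    if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(f))):
        return SegmentValidity(False, ValidityReason.DEGENERATE)
    # α is produced along increasing q and must be monotone (decreasing);
    # a direction reversal is a fold in the (α, f) curve.
    d_alpha = np.diff(alpha)
    if np.any(d_alpha > convexity_tol):
        return SegmentValidity(False, ValidityReason.NON_CONVEX)
    # unimodality of f along the α ordering: rise then fall
    order = np.argsort(alpha)
    f_sorted = f[order]
    df = np.diff(f_sorted)
    rising = True
    for step in df:
        if rising:
            if step < -convexity_tol:
                rising = False
        elif step > convexity_tol:
            return SegmentValidity(False, ValidityReason.NON_CONVEX)
    omega = float(alpha.max() - alpha.min())
    if omega < width_min:
        return SegmentValidity(False, ValidityReason.WIDTH_BELOW_MIN)
    return SegmentValidity(True, ValidityReason.OK)


def analyze_segment(values: np.ndarray, *, scales: np.ndarray | None = None,
                    q_grid: np.ndarray | None = None, detrend_order: int = 1,
                    width_min: float = 0.05, convexity_tol: float = 0.01,
                    ) -> tuple[MultifractalSpectrum | None,
                               SpectrumFeatures | None, SegmentValidity]:
    """MFDFA one segment end to end: spectrum, features, validity verdict."""
    try:
        surface = mfdfa_fluctuations(values, scales, q_grid, detrend_order)
    except DegenerateSeriesError:
        return None, None, SegmentValidity(False, ValidityReason.DEGENERATE)
    spectrum = singularity_spectrum(surface)
    validity = check_validity(spectrum, width_min, convexity_tol)
    if not validity.valid:
        return spectrum, None, validity
    return spectrum, spectrum_features(spectrum), validity
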