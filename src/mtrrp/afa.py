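"""Adaptive fractal analysis (AFA) of the Hurst exponent.

AFA estimates the Hurst exponent H of a self-similar process from the
root-mean-square residual F(W) between the integrated profile u(i) and an
adaptively stitched global trend v(i), computed at a ladder of odd window
sizes W = 2h + 1:

    F(W) = [ (1/N) * sum_i (u(i) - v(i))^2 ]^(1/2)  ~  W^H,

so H is the slope of log2 F(W) against log2 W. The trend is built from
overlapping local polynomial fits (order 1 by default) on windows of
length W that step by half a window; in each overlap the two local fits
are blended with linearly decaying, center-peaked weights, which makes the
stitched trend agree at segment junctions.

The input convention matters: ``u`` must be the integrated profile (an
fBm-like path). Pass ``input_is_increments=True`` for increment-like data
(fGn, returns) to integrate first — feeding increments straight in is the
classic off-by-one-in-H mistake.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .signals import ParameterError, TimeSeries

logger = logging.getLogger("mtrrp")


class WindowError(ValueError):
    """The window ladder does not fit the series."""


class DegenerateFitError(ValueError):
    """The detrending residuals vanish (series exactly polynomial)."""


@dataclass(frozen=True)
class AFAFit:
    window_sizes: np.ndarray   # odd, strictly increasing
    fluctuations: np.ndarray   # F(W) > 0
    hurst: float               # slope of log2 F vs log2 W
    r_squared: float


def integrate(series: TimeSeries | np.ndarray) -> np.ndarray:
    """Cumulative-sum profile X(i) = sum_{j<=i} x(j) (fGn -> fBm)."""
    x = series.samples if isinstance(series, TimeSeries) else np.asarray(series, float)
    if x.size == 0:
        raise ParameterError("cannot integrate an empty series")
    return np.cumsum(x)


def default_window_ladder(n: int) -> np.ndarray:
    """Odd window sizes growing dyadically, 5 up to n // 8."""
    sizes = []
    w = 5
    while w <= n // 8:
        sizes.append(w)
        w = 2 * (w - 1) + 1
    if len(sizes) < 3:
        raise WindowError(f"series of length {n} is too short for an AFA ladder")
    return np.asarray(sizes, dtype=int)


def _adaptive_trend(u: np.ndarray, w: int, order: int) -> np.ndarray:
    """Global trend from overlapping local polynomial fits of length w.

    Segments start every (w-1)//2 samples; a final segment anchored at the
    series end covers any remainder. Consecutive fits are blended over
    their overlap with a linear ramp, so shared junction samples receive
    identical values from both fits.
    """
    n = u.size
    half = (w - 1) // 2
    starts = list(range(0, n - w + 1, half))
    if starts[-1] != n - w:
        starts.append(n - w)
    starts = np.asarray(starts)
    t = np.arange(w, dtype=float)
    seg = u[starts[:, None] + np.arange(w)]          # (n_seg, w)
    coeffs = np.polynomial.polynomial.polyfit(t, seg.T, order)
    fitted = np.polynomial.polynomial.polyval(t, coeffs, tensor=True)
    fitted = np.atleast_2d(fitted)                   # (n_seg, w)

    v = np.empty(n)
    v[:w] = fitted[0]
    for j in range(1, len(starts)):
        s, prev = starts[j], starts[j - 1]
        ov = prev + w - s                            # overlap length >= 2
        ramp = np.arange(ov) / (ov - 1)
        v[s:s + ov] = (1 - ramp) * fitted[j - 1][s - prev:] + ramp * fitted[j][:ov]
        v[s + ov:s + w] = fitted[j][ov:]
    return v


def afa_fit(series: TimeSeries | np.ndarray,
            window_sizes: np.ndarray | None = None,
            detrend_order: int = 1,
            input_is_increments: bool = False) -> AFAFit:
    """Run AFA and return the fitted Hurst exponent.

    ``series`` is taken as the integrated profile unless
    ``input_is_increments`` is set, in which case it is cumulatively summed
    first. The largest window must not exceed a quarter of the series
    length.
    """
    x = series.samples if isinstance(series, TimeSeries) else np.asarray(series, float)
    if input_is_increments:
        logger.debug("afa_fit: integrating increment input into a profile")
        u = integrate(x)
    else:
        u = np.asarray(x, dtype=float)
    n = u.size
    windows = (default_window_ladder(n) if window_sizes is None
               else np.asarray(window_sizes, dtype=int))
    if windows.size < 3:
        raise WindowError("need at least 3 window sizes for the log-log fit")
    if np.any(windows[1:] <= windows[:-1]):
        raise WindowError("window sizes must be strictly increasing")
    if np.any(windows % 2 == 0) or np.any(windows < 3):
        raise WindowError("window sizes must be odd and >= 3")
    if windows[-1] > n // 4:
        raise WindowError(
            f"largest window {windows[-1]} exceeds n/4 = {n // 4}")
    if detrend_order < 0 or detrend_order >= windows[0]:
        raise ParameterError("detrend_order must be in [0, smallest window)")

    fluct = np.empty(windows.size)
    for i, w in enumerate(windows):
        v = _adaptive_trend(u, int(w), detrend_order)
        fluct[i] = np.sqrt(np.mean((u - v) ** 2))
    tol = 1e-10 * (float(np.std(u)) + 1e-300)  # numerically-zero residuals
    if np.any(fluct <= tol):
        raise DegenerateFitError(
            "zero detrending residuals: the series is exactly polynomial")

    res = _stats.linregress(np.log2(windows), np.log2(fluct))
    return AFAFit(window_sizes=windows, fluctuations=fluct,
                  hurst=float(res.slope), r_squared=float(res.rvalue ** 2))
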