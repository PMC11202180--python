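"""Multi-threshold recurrence rate curves and the derived metrics.

The multi-threshold recurrence rate plot (MTRRP) evaluates the recurrence
rate of a min-max normalized series over an increasing ladder of thresholds

    eps_k = eps_min + k * Q * sigma,   eps_k <= 1,

where sigma is the standard deviation of the normalized series. Three
scalar summaries are read off the curve:

* Recurrence Rate Gradient (RRG): OLS slope of RR against eps over the
  initial, pre-plateau segment — high values indicate noise-like local
  randomness;
* Recurrence Hurst (RH): Hurst-like exponent under the model
  RR(eps) = alpha * (1 - RH * ln eps) with alpha a user-chosen constant
  (0.5 by default). The default estimator reads RH off the model's
  log-slope, RH = -(d RR / d ln eps) / alpha, fitted over the pre-plateau
  region; pointwise estimates h_k = (1 - RR_k / alpha) / ln(eps_k)
  aggregated by median or mean are available as alternatives. For
  normalized data ln eps < 0 below eps = 1, so RH comes out negative for
  monotonically rising curves; values are reported as computed, with no
  sign flip — only the ordering across signals carries meaning;
* Recurrence Complexity (RC): the product RRG * RH, joining local
  randomness with long-range persistence.

``fit_rr_model`` additionally fits (alpha, RH) jointly by least squares.
With pair counting (``counting="pairs"`` in :func:`compute_mtrrp`, each
recurrent pair counted once among all n^2 cells, saturating near 1/2)
this calibration recovers the model constant alpha ~ 0.5 for classical
Brownian motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .recurrence import (DegenerateInputError, EmbeddingConfig, embed,
                         recurrence_rates, select_delay)
from .signals import ParameterError, TimeSeries

logger = logging.getLogger("mtrrp")

DEFAULT_EPS_MIN = 0.1
DEFAULT_Q = 0.3
DEFAULT_ALPHA = 0.5
DEFAULT_PLATEAU_FRACTION = 0.95
DEFAULT_EPOCH_LENGTH = 2000

_FP_SLACK = 1e-9


class ScheduleError(ValueError):
    """The threshold ladder cannot be built as requested."""


class FitError(ValueError):
    """Too few usable curve points for a regression."""


def normalize(series: TimeSeries | np.ndarray) -> TimeSeries:
    """Min-max normalize a series onto [0, 1]; constant series are rejected."""
    if isinstance(series, TimeSeries):
        x, fs, label = series.samples, series.sampling_rate, series.label
    else:
        x, fs, label = np.asarray(series, float), None, ""
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateInputError("constant series cannot be normalized")
    return TimeSeries((x - lo) / (hi - lo), sampling_rate=fs, label=label)


@dataclass(frozen=True)
class ThresholdSchedule:
    eps_min: float
    q: float
    sigma: float
    thresholds: np.ndarray

    @property
    def step(self) -> float:
        return self.q * self.sigma


def build_schedule(series_normalized: TimeSeries | np.ndarray,
                   eps_min: float = DEFAULT_EPS_MIN,
                   q: float = DEFAULT_Q) -> ThresholdSchedule:
    """Threshold ladder eps_k = eps_min + k*q*sigma, truncated at 1.0.

    ``sigma`` is the standard deviation of the (already normalized) series,
    so the ladder adapts to the data's variability. At least 3 thresholds
    must fit in (0, 1].
    """
    x = (series_normalized.samples if isinstance(series_normalized, TimeSeries)
         else np.asarray(series_normalized, float))
    if not (0 < eps_min < 1):
        raise ParameterError(f"eps_min must be in (0, 1), got {eps_min}")
    if q <= 0:
        raise ScheduleError(f"threshold factor Q must be > 0, got {q}")
    sigma = float(x.std())
    if sigma == 0:
        raise DegenerateInputError("constant series has sigma = 0")
    step = q * sigma
    n_steps = int(np.floor((1.0 - eps_min) / step + _FP_SLACK))
    thresholds = eps_min + step * np.arange(n_steps + 1)
    if thresholds.size < 3:
        raise ScheduleError(
            f"only {thresholds.size} thresholds fit in (0, 1] with "
            f"Q={q:g}, sigma={sigma:.3g}; use a smaller Q")
    return ThresholdSchedule(eps_min=float(eps_min), q=float(q), sigma=sigma,
                             thresholds=thresholds)


@dataclass(frozen=True)
class MTRRPCurve:
    """An MTRRP: recurrence rate at each threshold of the schedule.

    ``alpha`` is the model constant of the RR(eps) relation (0.5 for
    classical Brownian motion). Construction does not validate rate
    monotonicity, so exactly synthesized model curves (which decrease in
    eps for RH > 0) can round-trip through the estimators.
    """

    thresholds: np.ndarray
    rates: np.ndarray
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, float)
        r = np.asarray(self.rates, float)
        if t.size != r.size:
            raise ParameterError("thresholds and rates must have equal length")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "rates", r)


def compute_mtrrp(series: TimeSeries | np.ndarray,
                  embedding: EmbeddingConfig | None = None,
                  eps_min: float = DEFAULT_EPS_MIN,
                  q: float = DEFAULT_Q,
                  norm: str = "euclidean",
                  theiler: int = 0,
                  epoch_length: int | None = None,
                  alpha: float = DEFAULT_ALPHA,
                  counting: str = "matrix") -> MTRRPCurve:
    """Build the MTRRP of one series.

    The series is min-max normalized, the threshold ladder is derived from
    its normalized standard deviation, and RR is evaluated at every
    threshold. When ``embedding`` is None, m = 2 with tau from the
    autocorrelation method (falling back to tau = 1 when no 1/e crossing
    exists within lag n/4).

    ``counting`` selects the recurrence-rate convention: ``"matrix"``
    counts every cell of the symmetric matrix including the diagonal
    (saturates at 1); ``"pairs"`` counts each off-diagonal recurrent pair
    once among all n^2 cells (saturates near 1/2), the convention under
    which the model constant of classical Brownian motion is ~ 0.5.

    Long series are split into non-overlapping epochs of ``epoch_length``
    samples and the per-epoch recurrence rates are averaged per threshold;
    with ``epoch_length=None`` epoching kicks in automatically above 5000
    samples (using 2000-sample epochs) to keep the O(n^2) distance
    computation tractable.
    """
    if counting not in ("matrix", "pairs"):
        raise ParameterError(f"counting must be 'matrix' or 'pairs', got {counting!r}")
    if counting == "pairs" and theiler > 0:
        raise ParameterError("pair counting is defined for theiler = 0 only")
    normed = normalize(series)
    x = normed.samples
    schedule = build_schedule(normed, eps_min=eps_min, q=q)
    if embedding is None:
        try:
            embedding = EmbeddingConfig(m=2, tau=select_delay(x))
        except (ParameterError, ValueError):
            embedding = EmbeddingConfig(m=2, tau=1)

    n = x.size
    if epoch_length is None:
        epoch_length = DEFAULT_EPOCH_LENGTH if n > 5000 else n
    if epoch_length < 2:
        raise ParameterError("epoch_length must be >= 2 samples")
    n_epochs = max(1, n // epoch_length)
    rates = np.zeros(schedule.thresholds.size)
    for e in range(n_epochs):
        chunk = x[e * epoch_length:(e + 1) * epoch_length] if n_epochs > 1 else x
        ps = embed(chunk, embedding)
        rr = recurrence_rates(ps, schedule.thresholds, norm=norm,
                              theiler=theiler)
        if counting == "pairs":
            nv = len(ps.vectors)
            rr = (rr * nv * nv - nv) / (2 * nv * nv)
        rates += rr
    rates /= n_epochs
    return MTRRPCurve(thresholds=schedule.thresholds, rates=rates,
                      embedding=embedding, alpha=alpha)


# ---------------------------------------------------------------------------
# Derived metrics
# ---------------------------------------------------------------------------

def _plateau_cutoff(curve: MTRRPCurve, plateau_fraction: float) -> float:
    """Smallest threshold whose RR reaches ``plateau_fraction`` of the final RR."""
    target = plateau_fraction * curve.rates[-1]
    hit = np.nonzero(curve.rates >= target - _FP_SLACK)[0]
    return float(curve.thresholds[hit[0]]) if hit.size else float(curve.thresholds[-1])


def recurrence_rate_gradient(curve: MTRRPCurve,
                             fit_strategy: str = "per_series_plateau",
                             plateau_fraction: float = DEFAULT_PLATEAU_FRACTION,
                             uniform_max_eps: float | None = None) -> float:
    """OLS slope of RR against eps over the initial segment of the curve.

    The fit cutoff is either a uniform maximum threshold
    (``fit_strategy='uniform_max'``) or the per-series stabilization point:
    the smallest threshold where RR reaches ``plateau_fraction`` of the
    final recurrence rate.
    """
    if fit_strategy == "uniform_max":
        if uniform_max_eps is None:
            raise ParameterError("uniform_max strategy needs uniform_max_eps")
        cutoff = float(uniform_max_eps)
    elif fit_strategy == "per_series_plateau":
        cutoff = _plateau_cutoff(curve, plateau_fraction)
    else:
        raise ParameterError(f"unknown fit strategy {fit_strategy!r}")
    mask = curve.thresholds <= cutoff + _FP_SLACK
    if np.count_nonzero(mask) < 3:
        raise FitError(
            f"only {np.count_nonzero(mask)} curve points at or below the fit "
            f"cutoff {cutoff:g}; need >= 3")
    slope = np.polyfit(curve.thresholds[mask], curve.rates[mask], 1)[0]
    return float(slope)


def _rh_points(curve: MTRRPCurve, plateau_fraction: float) -> np.ndarray:
    """Indices of thresholds usable for per-threshold RH estimates."""
    valid = (curve.thresholds < 1.0 - _FP_SLACK) & (curve.rates < 1.0)
    n_skipped = np.count_nonzero(~valid)
    if n_skipped:
        logger.debug("recurrence_hurst: skipping %d saturated/eps=1 points",
                     n_skipped)
    cutoff = _plateau_cutoff(curve, plateau_fraction)
    pre = valid & (curve.thresholds <= cutoff + _FP_SLACK)
    # the plateau cutoff only applies when it leaves a usable fit region
    # (exact model curves decrease in eps, collapsing the cutoff to the
    # first point)
    return pre if np.count_nonzero(pre) >= 3 else valid


def pointwise_recurrence_hurst(rr: float | np.ndarray, epsilon: float | np.ndarray,
                               alpha: float = DEFAULT_ALPHA):
    """Single-threshold RH estimate h = (1 - RR/alpha) / ln(eps); exact
    algebraic inverse of the model at one point (h = 0 when RR = alpha)."""
    return (1.0 - np.asarray(rr, float) / alpha) / np.log(np.asarray(epsilon, float))


def recurrence_hurst(curve: MTRRPCurve, aggregator: str = "slope",
                     plateau_fraction: float = DEFAULT_PLATEAU_FRACTION) -> float:
    """Hurst-like exponent from the MTRRP model RR = alpha*(1 - RH*ln eps).

    The default ``"slope"`` estimator treats alpha as the user-chosen model
    constant and reads RH off the regression of RR on ln(eps) over the
    usable pre-plateau points: RH = -slope / alpha. The ``"median"`` /
    ``"mean"`` aggregators instead combine the pointwise estimates
    h_k = (1 - RR_k/alpha) / ln(eps_k); the slope form is the default
    because its ordering tracks the generator Hurst exponent across fBm
    sweeps far more faithfully (the pointwise form is dominated by the
    near-saturation blow-up of h_k).

    Points with eps = 1 (ln eps = 0) or RR = 1 are skipped. For exact
    model curves both estimators recover RH exactly.
    """
    if aggregator not in ("slope", "median", "mean"):
        raise ParameterError(
            f"aggregator must be 'slope', 'median' or 'mean', got {aggregator!r}")
    keep = _rh_points(curve, plateau_fraction)
    n_keep = int(np.count_nonzero(keep))
    if n_keep == 0:
        raise DegenerateInputError(
            "no usable curve points (all thresholds saturated or at eps = 1)")
    eps = curve.thresholds[keep]
    rr = curve.rates[keep]
    if aggregator == "slope":
        if n_keep < 2:
            raise FitError("slope estimator needs >= 2 usable curve points")
        slope = np.polyfit(np.log(eps), rr, 1)[0]
        return float(-slope / curve.alpha)
    h = pointwise_recurrence_hurst(rr, eps, curve.alpha)
    return float(np.median(h) if aggregator == "median" else np.mean(h))


def recurrence_complexity(rrg: float, rh: float) -> float:
    """Recurrence Complexity: the product of RRG and RH."""
    return rrg * rh


@dataclass(frozen=True)
class MetricTriple:
    """The three MTRRP summaries of one series; ``rc == rrg * rh`` exactly."""

    rrg: float
    rh: float
    rc: float


def metric_triple(curve: MTRRPCurve,
                  fit_strategy: str = "per_series_plateau",
                  plateau_fraction: float = DEFAULT_PLATEAU_FRACTION,
                  uniform_max_eps: float | None = None,
                  aggregator: str = "slope") -> MetricTriple:
    """Compute RRG, RH and RC together from one MTRRP curve."""
    rrg = recurrence_rate_gradient(curve, fit_strategy=fit_strategy,
                                   plateau_fraction=plateau_fraction,
                                   uniform_max_eps=uniform_max_eps)
    rh = recurrence_hurst(curve, aggregator=aggregator,
                          plateau_fraction=plateau_fraction)
    return MetricTriple(rrg=rrg, rh=rh, rc=recurrence_complexity(rrg, rh))


def fit_rr_model(curve: MTRRPCurve,
                 plateau_fraction: float = DEFAULT_PLATEAU_FRACTION) -> tuple[float, float]:
    """Jointly fit (alpha, RH) in RR(eps) = alpha*(1 - RH*ln eps).

    The model is linear in (alpha, beta) with beta = -alpha*RH, so the
    least-squares solution over the pre-plateau points is the regression of
    RR on ln eps; returns ``(alpha, rh)`` with alpha the value of the model
    at eps = 1.
    """
    keep = _rh_points(curve, plateau_fraction)
    if np.count_nonzero(keep) < 3:
        raise FitError("need >= 3 usable points to fit the RR model")
    logeps = np.log(curve.thresholds[keep])
    rr = curve.rates[keep]
    beta, alpha = np.polyfit(logeps, rr, 1)
    if alpha == 0:
        raise FitError("degenerate fit: alpha = 0")
    return float(alpha), float(-beta / alpha)
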