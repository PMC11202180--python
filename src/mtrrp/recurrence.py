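"""Phase-space reconstruction and recurrence plots.

A recurrence plot marks time pairs (i, j) whose delay-embedded states lie
within a distance threshold eps of each other:

    R[i, j] = 1  if  dist(X_i, X_j) <= eps  (and |i - j| >= theiler),

and the recurrence rate RR is the fraction of marked cells among the
counted cells. The threshold comparison is inclusive and the diagonal is
counted when the Theiler window is 0, so RR(eps) is a non-decreasing step
function of eps with RR -> 1 as eps exceeds the largest pairwise distance.

The full n x n matrix is only materialized up to a configurable size cap;
above it, recurrence rates are accumulated blockwise without storing the
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

from .signals import ParameterError, TimeSeries

#: Largest phase-space size for which a dense recurrence matrix is built.
DEFAULT_MATRIX_CAP = 5000

#: Block edge for the out-of-core recurrence-rate accumulation.
_BLOCK = 2048


class EmbeddingError(ValueError):
    """The series is too short for the requested embedding."""


class SelectionError(ValueError):
    """Automatic embedding-parameter selection found no qualifying value."""


class DegenerateInputError(ValueError):
    """The input leaves nothing to compute (e.g. no counted cells)."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """Time-delay embedding parameters: dimension ``m`` and delay ``tau``."""

    m: int = 2
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.tau < 1:
            raise ParameterError(f"delay tau must be >= 1, got {self.tau}")


@dataclass(frozen=True)
class PhaseSpace:
    """Delay-embedded trajectory: ``vectors[i] = (x_i, x_{i+tau}, ...)``."""

    vectors: np.ndarray  # (n_vectors, m)
    source_length: int


@dataclass(frozen=True)
class RecurrenceMatrix:
    entries: np.ndarray  # square boolean
    epsilon: float
    norm: str
    theiler: int


def embed(series: TimeSeries | np.ndarray, config: EmbeddingConfig) -> PhaseSpace:
    """Delay-embed a scalar series into ``m``-dimensional phase space.

    Produces ``n - (m - 1) * tau`` vectors; raises :class:`EmbeddingError`
    when the series is too short to produce at least two.
    """
    x = series.samples if isinstance(series, TimeSeries) else np.asarray(series, float)
    n = x.size
    m, tau = config.m, config.tau
    span = (m - 1) * tau
    if n <= span:
        raise EmbeddingError(
            f"series of length {n} cannot be embedded with m={m}, tau={tau} "
            f"(needs length > {span})")
    count = n - span
    vectors = np.lib.stride_tricks.sliding_window_view(x, span + 1)[:, ::tau] \
        if m > 1 else x[:, None]
    vectors = np.ascontiguousarray(vectors[:count])
    return PhaseSpace(vectors=vectors, source_length=n)


# ---------------------------------------------------------------------------
# Embedding-parameter selection
# ---------------------------------------------------------------------------

def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(max(2 * x.size, 2))))
    f = np.fft.rfft(x, nfft)
    full = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    if full[0] <= 0:
        raise DegenerateInputError("constant series has no autocorrelation")
    return full / full[0]


def _mutual_information(x: np.ndarray, lag: int, bins: int = 16) -> float:
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def _select_tau(x: np.ndarray, method: str) -> int:
    max_lag = x.size // 4
    if method == "autocorrelation":
        acf = _autocorrelation(x, max_lag)
        below = np.nonzero(acf < 1.0 / np.e)[0]
        if below.size == 0:
            raise SelectionError(
                f"autocorrelation never drops below 1/e within lag {max_lag}")
        return int(below[0])
    if method == "mutual_information":
        prev = _mutual_information(x, 1)
        for lag in range(2, max_lag + 1):
            cur = _mutual_information(x, lag)
            if cur > prev:  # lag-1 was a local minimum
                return lag - 1
            prev = cur
        raise SelectionError(
            f"mutual information has no local minimum within lag {max_lag}")
    raise ParameterError(f"unknown tau method {method!r}")


def select_delay(series: TimeSeries | np.ndarray,
                 tau_method: str = "autocorrelation") -> int:
    """Delay alone: the autocorrelation 1/e crossing or the first local
    minimum of the lagged mutual information (searched up to lag n/4)."""
    x = series.samples if isinstance(series, TimeSeries) else np.asarray(series, float)
    return max(1, _select_tau(x, tau_method))


def _fnn_fraction(x: np.ndarray, m: int, tau: int, rtol: float = 15.0) -> float:
    """Kennel false-nearest-neighbour fraction for dimension m -> m + 1."""
    span_next = m * tau
    if x.size <= span_next + 1:
        raise EmbeddingError("series too short for FNN at this dimension")
    ps = embed(x, EmbeddingConfig(m=m, tau=tau))
    vecs = ps.vectors[: x.size - span_next]  # need x[i + m*tau] for the test
    if len(vecs) < 2:
        raise EmbeddingError("series too short for FNN at this dimension")
    tree = cKDTree(vecs)
    dist, nn = tree.query(vecs, k=2)
    dist, nn = dist[:, 1], nn[:, 1]
    nxt = x[span_next:][: len(vecs)]
    # zero-distance neighbours (exact repeats) are true neighbours only if
    # the next coordinate also agrees
    floor = 1e-12 * max(float(np.std(x)), 1e-30)
    false = np.abs(nxt - nxt[nn]) > rtol * np.maximum(dist, floor)
    return float(np.mean(false))


def select_embedding_params(series: TimeSeries | np.ndarray,
                            tau_method: str = "autocorrelation",
                            fnn_threshold: float = 0.01,
                            max_dim: int = 10) -> EmbeddingConfig:
    """Choose (m, tau): tau from the autocorrelation 1/e crossing or the
    first local minimum of the lagged mutual information; m as the smallest
    dimension whose false-nearest-neighbour fraction falls below
    ``fnn_threshold`` (capped at ``max_dim``).
    """
    x = series.samples if isinstance(series, TimeSeries) else np.asarray(series, float)
    if x.size < 256:
        raise ParameterError("parameter selection needs at least 256 samples")
    tau = max(1, _select_tau(x, tau_method))
    m = max_dim
    for cand in range(1, max_dim + 1):
        if _fnn_fraction(x, cand, tau) < fnn_threshold:
            m = cand
            break
    return EmbeddingConfig(m=m, tau=tau)


# ---------------------------------------------------------------------------
# Recurrence matrix and recurrence rate
# ---------------------------------------------------------------------------

def _check_norm(norm: str) -> str:
    if norm not in ("euclidean", "chebyshev"):
        raise ParameterError(f"norm must be 'euclidean' or 'chebyshev', got {norm!r}")
    return norm


def recurrence_matrix(ps: PhaseSpace, epsilon: float, norm: str = "euclidean",
                      theiler: int = 0,
                      matrix_cap: int = DEFAULT_MATRIX_CAP) -> RecurrenceMatrix:
    """Dense thresholded recurrence matrix (inclusive comparison).

    Symmetric; the main diagonal is all ones when ``theiler`` is 0, and the
    band ``|i - j| < theiler`` is zeroed otherwise.
    """
    _check_norm(norm)
    if epsilon < 0:
        raise ParameterError("epsilon must be >= 0")
    if theiler < 0:
        raise ParameterError("theiler must be >= 0")
    n = len(ps.vectors)
    if n > matrix_cap:
        raise ParameterError(
            f"{n} vectors exceed the dense-matrix cap {matrix_cap}; "
            "use recurrence_rates() for the blockwise path")
    d = cdist(ps.vectors, ps.vectors, metric=norm)
    entries = d <= epsilon
    if theiler > 0:
        offs = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        entries &= offs >= theiler
    return RecurrenceMatrix(entries=entries, epsilon=float(epsilon),
                            norm=norm, theiler=int(theiler))


def _counted_cells(n: int, theiler: int) -> int:
    if theiler <= 0:
        return n * n
    excluded = n  # diagonal
    for d in range(1, min(theiler, n)):
        excluded += 2 * (n - d)
    return n * n - excluded


def recurrence_rate(rm: RecurrenceMatrix) -> float:
    """Fraction of recurrence points among counted cells (Theiler band excluded)."""
    n = rm.entries.shape[0]
    counted = _counted_cells(n, rm.theiler)
    if counted <= 0:
        raise DegenerateInputError("Theiler window excludes every cell")
    return float(np.count_nonzero(rm.entries)) / counted


def recurrence_rates(ps: PhaseSpace, epsilons: np.ndarray, norm: str = "euclidean",
                     theiler: int = 0) -> np.ndarray:
    """RR at each threshold, without materializing the recurrence matrix.

    Pairwise distances are streamed in blocks, so memory stays at
    O(block^2) regardless of the trajectory length. Counts use the upper
    triangle only and exploit symmetry.
    """
    _check_norm(norm)
    eps = np.asarray(epsilons, dtype=float)
    if np.any(eps < 0):
        raise ParameterError("epsilon must be >= 0")
    vecs = ps.vectors
    n = len(vecs)
    counted = _counted_cells(n, theiler)
    if counted <= 0:
        raise DegenerateInputError("Theiler window excludes every cell")
    thr = eps if norm == "chebyshev" else eps ** 2
    metric = "chebyshev" if norm == "chebyshev" else "sqeuclidean"

    counts = np.zeros(eps.size, dtype=np.int64)
    if n <= _BLOCK:
        d = pdist(vecs, metric=metric)
        if theiler > 1:
            iu, ju = np.triu_indices(n, k=1)
            d = d[ju - iu >= theiler]
        for k, t in enumerate(thr):
            counts[k] = np.count_nonzero(d <= t)
    else:
        for i0 in range(0, n, _BLOCK):
            bi = vecs[i0:i0 + _BLOCK]
            d0 = pdist(bi, metric=metric)
            if theiler > 1:
                iu, ju = np.triu_indices(len(bi), k=1)
                d0 = d0[ju - iu >= theiler]
            for k, t in enumerate(thr):
                counts[k] += np.count_nonzero(d0 <= t)
            for j0 in range(i0 + _BLOCK, n, _BLOCK):
                bj = vecs[j0:j0 + _BLOCK]
                d = cdist(bi, bj, metric=metric)
                if theiler > 1:
                    offs = np.abs(np.subtract.outer(
                        np.arange(i0, i0 + len(bi)), np.arange(j0, j0 + len(bj))))
                    d = d[offs >= theiler]
                for k, t in enumerate(thr):
                    counts[k] += np.count_nonzero(d <= t)
    diag = n if theiler <= 0 else 0
    return (diag + 2 * counts.astype(float)) / counted
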