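"""Synthetic signal generators.

Everything downstream (recurrence analysis, AFA, the EEG feature pipeline)
is exercised on signals produced here, so the generators are first-class,
deterministic functions of their spec and seed:

* fractional Brownian motion (fBm) at a chosen Hurst exponent, via exact
  circulant embedding of the fractional-Gaussian-noise covariance
  (Davies-Harte), with a Cholesky fallback for short series;
* reference signals: white noise, random walk, harmonic oscillation,
  and the chaotic logistic map at r = 4;
* a 19-channel EEG-like cohort (10-20 montage) built from band-limited
  oscillations plus a fractional-noise floor whose Hurst exponent can be
  made group-specific in the occipital channels, so a real group effect
  in the recurrence metrics exists by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger("mtrrp")

#: The 19 scalp electrodes of the standard 10-20 montage used throughout.
MONTAGE_10_20 = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T3", "T4", "T5", "T6",
    "Pz", "P3", "P4", "O1", "O2",
)

#: Occipital channels carrying the injected group effect by default.
OCCIPITAL = ("O1", "O2")


class ParameterError(ValueError):
    """A generator or analysis parameter is out of its valid range."""


@dataclass(frozen=True)
class TimeSeries:
    """One channel of uniformly sampled real values.

    ``sampling_rate`` is optional: abstract series (e.g. the logistic map)
    have no physical time base.
    """

    samples: np.ndarray
    sampling_rate: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ParameterError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("time series contains non-finite values")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class FbmSpec:
    """Specification of one fractional Brownian motion realization."""

    hurst: float
    n: int = 8192
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ParameterError(f"hurst must be in (0, 1), got {self.hurst}")
        if self.n < 64:
            raise ParameterError(f"n must be >= 64, got {self.n}")


def _fgn_covariance(hurst: float, n: int) -> np.ndarray:
    # autocovariance of unit-variance fractional Gaussian noise
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def _fgn_davies_harte(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray | None:
    """Exact fGn sample via circulant embedding; None if the embedding
    is not nonnegative definite (then the caller falls back to Cholesky)."""
    gamma = _fgn_covariance(hurst, n)
    row = np.concatenate([gamma, [0.0], gamma[:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        return None
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    a = rng.standard_normal(n + 1)
    b = rng.standard_normal(n - 1)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * a[0]
    w[n] = np.sqrt(lam[n] / m) * a[n]
    k = np.arange(1, n)
    w[k] = np.sqrt(lam[k] / (2 * m)) * (a[k] + 1j * b[k - 1])
    w[m - k] = np.conj(w[k])
    return np.fft.fft(w).real[:n]


def _fgn_cholesky(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    gamma = _fgn_covariance(hurst, n)
    cov = np.empty((n, n))
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov[:] = gamma[idx]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return chol @ rng.standard_normal(n)


def generate_fgn(hurst: float, n: int, seed: int) -> np.ndarray:
    """Unit-variance fractional Gaussian noise (the increment process of fBm)."""
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"hurst must be in (0, 1), got {hurst}")
    rng = np.random.default_rng(seed)
    out = _fgn_davies_harte(hurst, n, rng)
    if out is None:  # pragma: no cover - embedding is valid for all H in (0,1)
        logger.info("circulant embedding indefinite at H=%.3f, using Cholesky", hurst)
        out = _fgn_cholesky(hurst, n, rng)
    return out


def generate_fbm(spec: FbmSpec) -> TimeSeries:
    """Fractional Brownian motion path: the cumulative sum of fGn increments.

    The increments are stationary Gaussian with exact covariance, so the
    k-step increment variance scales as ``k**(2*hurst)``.
    """
    increments = generate_fgn(spec.hurst, spec.n, spec.seed)
    path = np.cumsum(increments)
    return TimeSeries(path, label=f"fbm(H={spec.hurst:g}, seed={spec.seed})")


_REFERENCE_KINDS = ("white_noise", "random_walk", "harmonic", "logistic_chaos")
_LOGISTIC_BURN_IN = 1000


def generate_reference(kind: str, n: int, params: dict | None = None,
                       seed: int = 0) -> TimeSeries:
    """Reference signals spanning the stochastic / periodic / chaotic classes.

    kind:
        ``white_noise``     i.i.d. standard Gaussian samples
        ``random_walk``     cumulative sum of white noise (memoryless, H = 0.5)
        ``harmonic``        sine wave, exactly periodic with integer
                            ``params["period"]`` samples
        ``logistic_chaos``  logistic map x -> 4 x (1 - x) after a 1000-step
                            burn-in, values in [0, 1]
    """
    if kind not in _REFERENCE_KINDS:
        raise ParameterError(f"unknown reference kind {kind!r}; one of {_REFERENCE_KINDS}")
    if n < 64:
        raise ParameterError(f"n must be >= 64, got {n}")
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "white_noise":
        x = rng.standard_normal(n)
    elif kind == "random_walk":
        x = np.cumsum(rng.standard_normal(n))
    elif kind == "harmonic":
        period = int(params.get("period", 64))
        if period < 2:
            raise ParameterError("harmonic period must be >= 2 samples")
        amplitude = float(params.get("amplitude", 1.0))
        # phase computed modulo the period so periodicity is bit-exact
        x = amplitude * np.sin(2 * np.pi * (np.arange(n) % period) / period)
    else:  # logistic_chaos
        x0 = float(params.get("x0", rng.uniform(0.1, 0.9)))
        v = x0
        for _ in range(_LOGISTIC_BURN_IN):
            v = 4.0 * v * (1.0 - v)
        x = np.empty(n)
        for i in range(n):
            x[i] = v
            v = 4.0 * v * (1.0 - v)
    return TimeSeries(x, label=f"{kind}(n={n}, seed={seed})")


# ---------------------------------------------------------------------------
# Synthetic EEG cohort
# ---------------------------------------------------------------------------

#: Oscillation amplitudes per band. Resting EEG is dominated by its
#: broadband 1/f-like background with an alpha-band peak on top; the
#: oscillatory bumps sit well below the noise floor (noise_amplitude=4)
#: so that the fractal background dominates the in-band power of every
#: analysis band, which is what lets a background Hurst difference
#: propagate into the band-limited recurrence metrics.
DEFAULT_BAND_AMPLITUDES = {
    "Delta": 0.5,
    "Theta": 0.4,
    "Alpha": 1.0,
    "Beta": 0.3,
    "Gamma": 0.2,
}

_BAND_EDGES = {
    "Delta": (0.5, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "Beta": (13.0, 30.0),
    "Gamma": (30.0, 45.0),
}

_MIN_EPOCH_SAMPLES = 512


@dataclass(frozen=True)
class SyntheticEEGSpec:
    """Configuration of the synthetic resting-state cohort.

    Each channel is a sum of band-limited oscillations (narrowband-filtered
    Gaussian noise in the conventional Delta..Gamma bands) plus a stationary
    fractional-Gaussian-noise floor. The noise floor in the occipital
    channels (O1, O2) uses a group-specific Hurst exponent, which is the
    injected, known-by-construction group effect; every other channel uses
    ``baseline_hurst`` in both groups.
    """

    n_per_group: int = 15
    groups: tuple[str, ...] = ("HC", "AD")
    channels: tuple[str, ...] = MONTAGE_10_20
    sampling_rate: float = 500.0
    duration: float = 300.0
    occipital_hurst_by_group: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.7, "AD": 0.3})
    baseline_hurst: float = 0.5
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    noise_amplitude: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("need at least 2 subjects per group")
        if set(self.occipital_hurst_by_group) != set(self.groups):
            raise ParameterError("occipital_hurst_by_group must cover every group")
        for h in (*self.occipital_hurst_by_group.values(), self.baseline_hurst):
            if not 0.0 < h < 1.0:
                raise ParameterError(f"Hurst exponents must be in (0, 1), got {h}")
        if self.duration * self.sampling_rate < _MIN_EPOCH_SAMPLES:
            raise ParameterError(
                f"duration x sampling_rate must be >= {_MIN_EPOCH_SAMPLES} samples")
        nyq = self.sampling_rate / 2.0
        for name in self.band_amplitudes:
            if name not in _BAND_EDGES:
                raise ParameterError(f"unknown band {name!r}")
            if _BAND_EDGES[name][1] >= nyq:
                raise ParameterError(
                    f"band {name} exceeds the Nyquist frequency {nyq:g} Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def _band_carrier(low: float, high: float, fs: float, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance narrowband oscillation: band-passed Gaussian noise."""
    sos = _sig.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_synthetic_eeg(spec: SyntheticEEGSpec) -> list:
    """Generate the synthetic cohort as a list of ``EEGRecording`` objects.

    Deterministic: per-subject, per-channel random streams are spawned from
    ``spec.seed`` with ``numpy.random.SeedSequence``, so identical specs give
    byte-identical recordings regardless of generation order.
    """
    from .eeg import EEGRecording  # deferred to avoid a module cycle

    n = spec.n_samples
    root = np.random.SeedSequence(spec.seed)
    subject_seqs = root.spawn(len(spec.groups) * spec.n_per_group)
    recordings = []
    idx = 0
    for group in spec.groups:
        for s in range(spec.n_per_group):
            subject_id = f"{group.lower()}{s + 1:02d}"
            chan_seqs = subject_seqs[idx].spawn(len(spec.channels))
            idx += 1
            data = np.empty((len(spec.channels), n))
            for c, chan in enumerate(spec.channels):
                rng = np.random.default_rng(chan_seqs[c])
                x = np.zeros(n)
                for band, amp in spec.band_amplitudes.items():
                    low, high = _BAND_EDGES[band]
                    x += amp * _band_carrier(low, high, spec.sampling_rate, n, rng)
                hurst = (spec.occipital_hurst_by_group[group]
                         if chan in OCCIPITAL else spec.baseline_hurst)
                noise = generate_fgn(hurst, n, rng.integers(2 ** 31))
                x += spec.noise_amplitude * noise / noise.std()
                data[c] = x
            recordings.append(EEGRecording(
                channels=spec.channels, data=data,
                sampling_rate=spec.sampling_rate,
                subject_id=subject_id, group=group))
    return recordings
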