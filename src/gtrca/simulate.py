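"""Synthetic multi-subject SSVEP-like group data with known ground truth.

The generator emulates joint frequency-phase modulated (JFPM) flicker
responses: condition ``c`` drives a source

    s_c(t) = Σ_{h=1..H} h^{-1} sin(2π h f_c t + h φ_c),

with frequencies ``f_start + c·f_step`` and phases ``c·phase_step``.  The
``1/h`` harmonic decay gives the low-frequency conditions the bimodal
waveforms typical of real flicker responses.  Each subject mixes the source
into channels through a fixed smooth random topography ``a_α`` (no forward
head model; the topographies are abstract).

Noise has two parts, mimicking ongoing background activity plus sensor
noise:

* spatially low-rank pink (1/f) background, generated as one continuous
  stream per subject so that it is stationary across trial boundaries, and
* white sensor noise drawn independently per (subject, trial).

The requested ``snr`` is the ratio of the per-trial RMS amplitude of the
signal ``a_α s_c`` to the RMS of the total noise.  Trials are concatenated
to form each subject's continuous recording, so the epochs exactly tile the
recording.  All randomness derives from the master seed through fixed
per-(subject, condition) stream keys: the same seed yields byte-identical
data, and changing A or K does not reshuffle unrelated streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import ConditionInfo, EpochSet, GroupDataset, SubjectRecording, epoch
from .preprocess import normalize_channels

__all__ = [
    "SyntheticParams",
    "SyntheticGroundTruth",
    "generate_group_ssvep",
    "generate_null",
    "desk_params",
    "benchmark_params",
    "full_scale_params",
]

# relative RMS weights of the two noise parts (pink background, white sensor)
_PINK_WEIGHT = 0.8
_WHITE_WEIGHT = 0.6


@dataclass
class SyntheticParams:
    """Generator configuration.

    Defaults describe a desk-scale group study: 5 subjects, 6 trials of 2 s
    at 250 Hz over 16 channels, 4 JFPM conditions starting at 8 Hz in
    0.2 Hz / 90° steps, 3 harmonics with 1/h decay, and a signal-to-noise
    amplitude ratio of 1.
    """

    A: int = 5
    K: int = 6
    C: int = 4
    n: int = 16
    fs: float = 250.0
    tau_seconds: float = 2.0
    f_start: float = 8.0
    f_step: float = 0.2
    phase_step: float = math.pi / 2
    n_harmonics: int = 3
    snr: float = 1.0
    noise_spatial_rank: int = 4
    seed: int = 0
    normalize: bool = True
    iti_seconds: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A", "K", "C", "n", "n_harmonics", "noise_spatial_rank"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fs <= 0 or self.tau_seconds <= 0 or self.f_start <= 0 or self.f_step < 0:
            raise ValueError("fs, tau_seconds, f_start must be positive; f_step non-negative")
        f_max = self.f_start + self.f_step * (self.C - 1)
        if self.fs <= 2.0 * f_max * self.n_harmonics:
            raise ValueError(
                f"sampling rate {self.fs} Hz cannot represent harmonic content up to "
                f"{f_max * self.n_harmonics} Hz"
            )
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be a non-negative 31-bit integer")
        if self.iti_seconds < 0:
            raise ValueError("iti_seconds must be non-negative")

    @property
    def tau(self) -> int:
        return int(round(self.tau_seconds * self.fs))

    @property
    def iti(self) -> int:
        """Inter-trial interval in samples (0: trials tile the recording)."""
        return int(round(self.iti_seconds * self.fs))

    def frequencies(self) -> np.ndarray:
        return self.f_start + self.f_step * np.arange(self.C)

    def phases(self) -> np.ndarray:
        return self.phase_step * np.arange(self.C)


@dataclass
class SyntheticGroundTruth:
    """What the generator actually injected, for parameter-recovery checks."""

    sources: np.ndarray  # (C, tau)
    mixing: np.ndarray  # (A, n)
    noise_sigma: float
    seed: int
    frequencies: np.ndarray = field(default_factory=lambda: np.array([]))


def desk_params(**overrides) -> SyntheticParams:
    """Desk-scale defaults (A=5, C=4, n=16)."""
    return replace(SyntheticParams(), **overrides)


def benchmark_params(**overrides) -> SyntheticParams:
    """Transfer/comparison benchmark: 10 subjects, 8 conditions at 8-15 Hz
    in 1 Hz steps, moderate noise (snr 0.5)."""
    base = SyntheticParams(A=10, C=8, f_step=1.0, snr=0.5)
    return replace(base, **overrides)


def full_scale_params(**overrides) -> SyntheticParams:
    """The full-scale configuration of the public 35-subject benchmark:
    64 channels, 40 conditions at 8-15.8 Hz in 0.2 Hz steps, 6 trials of
    5 s at 250 Hz."""
    base = SyntheticParams(A=35, C=40, n=64, K=6, fs=250.0, tau_seconds=5.0)
    return replace(base, **overrides)


def _smooth_topography(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random spatially smooth pattern over the channel axis, unit norm."""
    raw = rng.standard_normal(n)
    sigma = max(n / 8.0, 1.0)
    idx = np.arange(n)
    kernel = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / sigma) ** 2)
    v = kernel @ raw
    nrm = np.linalg.norm(v)
    if nrm == 0:  # astronomically unlikely; retry deterministically
        v = kernel @ rng.standard_normal(n)
        nrm = np.linalg.norm(v)
    return v / nrm


def _pink_series(rng: np.random.Generator, n_series: int, T: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit RMS per series."""
    freqs = np.fft.rfftfreq(T)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_series, freqs.size))
            + 1j * rng.standard_normal((n_series, freqs.size))) * scale
    x = np.fft.irfft(spec, n=T, axis=1)
    rms = np.sqrt((x**2).mean(axis=1, keepdims=True))
    return x / rms


def _sources(params: SyntheticParams) -> np.ndarray:
    t = np.arange(params.tau) / params.fs
    S = np.zeros((params.C, params.tau))
    for c, (f, ph) in enumerate(zip(params.frequencies(), params.phases())):
        for h in range(1, params.n_harmonics + 1):
            S[c] += np.sin(2 * math.pi * h * f * t + h * ph) / h
    return S


def _mixing(params: SyntheticParams) -> np.ndarray:
    return np.stack([
        _smooth_topography(np.random.default_rng([params.seed, 1, a]), params.n)
        for a in range(params.A)
    ])


def _subject_noise(params: SyntheticParams, c: int, a: int, T: int) -> np.ndarray:
    """Unit-RMS noise (n x T): per-subject pink background + per-trial white."""
    n = params.n
    seg = params.tau + params.iti
    rank = min(params.noise_spatial_rank, n)
    rng_bg = np.random.default_rng([params.seed, 2, c, a])
    B = np.stack([_smooth_topography(rng_bg, n) for _ in range(rank)], axis=1)  # (n, rank)
    pink = B @ _pink_series(rng_bg, rank, T)
    pink /= np.sqrt((pink**2).mean())
    white = np.empty((n, T))
    for k in range(T // seg):
        rng_k = np.random.default_rng([params.seed, 3, c, a, k])
        white[:, k * seg:(k + 1) * seg] = rng_k.standard_normal((n, seg))
    noise = _PINK_WEIGHT * pink + _WHITE_WEIGHT * white
    return noise / np.sqrt((noise**2).mean())


def _build_dataset(params: SyntheticParams, c: int, source: np.ndarray | None,
                   mixing: np.ndarray, cond: ConditionInfo) -> GroupDataset:
    tau = params.tau
    seg = tau + params.iti
    T = params.K * seg
    onsets = np.arange(params.K) * seg
    subjects = []
    for a in range(params.A):
        if source is None or params.snr == 0:
            X = _subject_noise(params, c, a, T)
        else:
            sig_trial = np.outer(mixing[a], source)  # (n, tau)
            X = np.zeros((params.n, T))
            for t0 in onsets:
                X[:, t0:t0 + tau] = sig_trial
            sig_rms = np.sqrt((sig_trial**2).mean())
            if not math.isinf(params.snr):
                X = X + (sig_rms / params.snr) * _subject_noise(params, c, a, T)
        if params.normalize:
            X = normalize_channels(X)
        rec = SubjectRecording(
            subject_id=f"sub{a:02d}",
            X=X,
            fs=params.fs,
            onsets=onsets,
            tau=tau,
        )
        subjects.append((rec, epoch(rec)))
    return GroupDataset(subjects=subjects, condition=cond)


def generate_group_ssvep(params: SyntheticParams | None = None) -> tuple[list[GroupDataset], SyntheticGroundTruth]:
    """Generate one GroupDataset per condition plus the injected ground truth."""
    params = params or SyntheticParams()
    sources = _sources(params)
    mixing = _mixing(params)
    freqs = params.frequencies()
    datasets = []
    for c in range(params.C):
        cond = ConditionInfo(condition_id=c, f_stim=float(freqs[c]), phase=float(params.phases()[c]))
        datasets.append(_build_dataset(params, c, sources[c], mixing, cond))
    sig_rms = np.sqrt((sources**2).mean())
    noise_sigma = 0.0 if math.isinf(params.snr) else float(sig_rms / max(params.snr, 1e-300))
    truth = SyntheticGroundTruth(
        sources=sources,
        mixing=mixing,
        noise_sigma=noise_sigma,
        seed=params.seed,
        frequencies=freqs,
    )
    return datasets, truth


def generate_null(params: SyntheticParams | None = None) -> list[GroupDataset]:
    """Same noise machinery with zero source amplitude: nothing is
    time-locked to the trial onsets."""
    params = params or SyntheticParams()
    freqs = params.frequencies()
    return [
        _build_dataset(
            params, c, None, np.zeros((params.A, params.n)),
            ConditionInfo(condition_id=c, f_stim=float(freqs[c]), phase=float(params.phases()[c])),
        )
        for c in range(params.C)
    ]
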