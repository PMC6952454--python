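"""Containers for multi-subject, multi-trial EEG data.

The analysis operates on two views of each subject's data: the continuous
recording ``X`` (channels x samples) from which the data covariance is
estimated, and the epoched view (trials x channels x samples) from which
inter-trial covariances are estimated.  Trial windows are 0-based and
half-open: trial ``k`` occupies samples ``[t_k, t_k + tau)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_float_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D (channels x samples), got shape {X.shape}")
    return X


@dataclass
class SubjectRecording:
    """Continuous multichannel EEG for one subject plus trial timing.

    Parameters
    ----------
    subject_id : str
        Identifier used in file layouts and exported tables.
    X : ndarray, shape (n_channels, T)
        Continuous data.  Unitless after channel normalization.
    fs : float
        Sampling rate in Hz.
    onsets : sequence of int
        Trial-onset sample indices ``t_k``; each window ``[t_k, t_k + tau)``
        must lie inside the recording.
    tau : int
        Trial length in samples.
    channel_labels : list of str, optional
        One label per channel; defaults to ``ch00, ch01, ...``.
    """

    subject_id: str
    X: np.ndarray
    fs: float
    onsets: np.ndarray
    tau: int
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = _as_float_matrix(self.X)
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if self.onsets.ndim != 1 or self.onsets.size < 1:
            raise ValueError("onsets must be a non-empty 1-D sequence of sample indices")
        self.tau = int(self.tau)
        n, T = self.X.shape
        if n < 1:
            raise ValueError("need at least one channel")
        if self.tau < 2:
            raise ValueError(f"trial length tau must be >= 2 samples, got {self.tau}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        bad = np.flatnonzero((self.onsets < 0) | (self.onsets + self.tau > T))
        if bad.size:
            k = int(bad[0])
            raise ValueError(
                f"onset #{k} (t={int(self.onsets[k])}) with tau={self.tau} falls outside "
                f"the recording of length T={T}"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(n)]
        if len(self.channel_labels) != n:
            raise ValueError("channel_labels length must match the number of channels")

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def n_trials(self) -> int:
        return int(self.onsets.size)


@dataclass
class EpochSet:
    """Windowed trials for one subject and condition: array (K, n, tau)."""

    trials: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.float64)
        if self.trials.ndim != 3:
            raise ValueError(
                f"trials must be 3-D (K, n_channels, tau), got shape {self.trials.shape}"
            )
        if self.trials.shape[0] < 1:
            raise ValueError("need at least one trial")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def K(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def tau(self) -> int:
        return self.trials.shape[2]


@dataclass
class ConditionInfo:
    """Stimulation condition: integer id, flicker frequency, and phase."""

    condition_id: int
    f_stim: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.f_stim <= 0:
            raise ValueError(f"f_stim must be positive, got {self.f_stim}")


@dataclass
class GroupDataset:
    """All subjects' data for one condition.

    ``subjects`` is a list of ``(SubjectRecording, EpochSet)`` pairs.  All
    subjects must share the trial length ``tau`` (component time courses are
    compared across subjects sample by sample); channel counts and trial
    counts may differ between subjects.
    """

    subjects: list[tuple[SubjectRecording, EpochSet]]
    condition: ConditionInfo

    def __post_init__(self) -> None:
        if len(self.subjects) < 1:
            raise ValueError("need at least one subject")
        taus = set()
        for rec, ep in self.subjects:
            if rec.n_channels != ep.n_channels:
                raise ValueError(
                    f"subject {rec.subject_id}: continuous data has {rec.n_channels} "
                    f"channels but epochs have {ep.n_channels}"
                )
            if rec.tau != ep.tau:
                raise ValueError(
                    f"subject {rec.subject_id}: recording tau={rec.tau} but epochs tau={ep.tau}"
                )
            taus.add(ep.tau)
        if len(taus) != 1:
            raise ValueError(f"all subjects must share the trial length tau, got {sorted(taus)}")

    @property
    def A(self) -> int:
        return len(self.subjects)

    @property
    def tau(self) -> int:
        return self.subjects[0][1].tau

    @property
    def fs(self) -> float:
        return self.subjects[0][0].fs

    def channel_counts(self) -> list[int]:
        return [rec.n_channels for rec, _ in self.subjects]


@dataclass
class PcaReduction:
    """Orthonormal basis from a PCA reduction, kept so that spatial filters
    and maps computed in the reduced space can be lifted back to channels."""

    basis: np.ndarray  # (n, m), orthonormal columns
    explained_fraction: float

    def __post_init__(self) -> None:
        self.basis = _as_float_matrix(self.basis, "basis")
        if not (0.0 < self.explained_fraction <= 1.0 + 1e-12):
            raise ValueError("explained_fraction must be in (0, 1]")
        G = self.basis.T @ self.basis
        if not np.allclose(G, np.eye(self.basis.shape[1]), atol=1e-8):
            raise ValueError("basis columns must be orthonormal")

    def lift(self, v: np.ndarray) -> np.ndarray:
        """Map a vector (filter or map) from the reduced space to channels."""
        return self.basis @ np.asarray(v, dtype=np.float64)


def epoch(rec: SubjectRecording) -> EpochSet:
    """Slice the continuous recording into trial windows.

    Trial ``k`` is ``X[:, t_k : t_k + tau]`` (0-based, half-open).  Onset
    validity is enforced by :class:`SubjectRecording`.
    """
    idx = rec.onsets[:, None] + np.arange(rec.tau)[None, :]
    trials = rec.X[:, idx]  # (n, K, tau)
    return EpochSet(trials=np.ascontiguousarray(trials.transpose(1, 0, 2)), fs=rec.fs)
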