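"""Preprocessing: channel normalization, zero-phase FIR bandpass, PCA reduction.

Conventions
-----------
* Variances use the population convention (divisor ``T``), so after
  :func:`normalize_channels` the diagonal of the data covariance
  ``Q = X X^T / T`` is exactly 1.
* The bandpass filter is a linear-phase Hamming-window FIR applied
  forward-backward (zero phase), preserving trial-locked latencies.
* The recommended order is filter -> normalize -> epoch.  Note this order is
  a convention of this package, not something the method itself prescribes.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datasets import PcaReduction, _as_float_matrix

__all__ = ["normalize_channels", "bandpass_filter", "reduce_dimensions"]


def normalize_channels(X: np.ndarray, channel_labels: list[str] | None = None) -> np.ndarray:
    """Scale each channel (row) to zero mean and unit population variance.

    Raises
    ------
    ValueError
        If a channel is constant (its variance is zero); such a channel
        would make the data covariance singular.
    """
    X = _as_float_matrix(X)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel to normalize")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population (divisor T)
    flat = np.flatnonzero(sd[:, 0] == 0.0)
    if flat.size:
        i = int(flat[0])
        name = channel_labels[i] if channel_labels else f"channel {i}"
        raise ValueError(f"constant channel cannot be normalized: {name}")
    return (X - mean) / sd


def fir_bandpass_taps(fs: float, lo: float = 0.5, hi: float = 49.5, transition: float = 1.0) -> np.ndarray:
    """Design the Hamming-window FIR bandpass used throughout.

    The number of taps follows the Hamming-window rule
    ``N ~= 3.3 / (transition / fs)``, rounded up to an odd integer so the
    filter has an exact linear phase (type I).
    """
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"need 0 < lo < hi < fs/2, got lo={lo}, hi={hi}, fs={fs}")
    if transition <= 0:
        raise ValueError("transition bandwidth must be positive")
    numtaps = int(np.ceil(3.3 * fs / transition))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def bandpass_filter(
    X: np.ndarray,
    fs: float,
    lo: float = 0.5,
    hi: float = 49.5,
    transition: float = 1.0,
) -> np.ndarray:
    """Zero-phase bandpass: Hamming-window FIR applied forward-backward.

    Default band 0.5-49.5 Hz with a 1 Hz transition removes baseline drift
    and line noise while keeping the SSVEP range intact.
    """
    X = _as_float_matrix(X)
    taps = fir_bandpass_taps(fs, lo, hi, transition)
    padlen = 3 * len(taps)
    if X.shape[1] <= padlen:
        raise ValueError(
            f"recording too short for zero-phase filtering: need more than {padlen} "
            f"samples for a {len(taps)}-tap filter, got {X.shape[1]}"
        )
    return signal.filtfilt(taps, [1.0], X, axis=1)


def reduce_dimensions(X: np.ndarray, explained_fraction: float = 0.9) -> tuple[np.ndarray, PcaReduction]:
    """Project channels onto the fewest principal components reaching the
    requested cumulative variance fraction.

    Returns the projected data (m x T) and the orthonormal basis so filters
    and scalp maps fitted in the reduced space can be lifted back to channel
    space with :meth:`PcaReduction.lift`.
    """
    X = _as_float_matrix(X)
    if not (0.0 < explained_fraction <= 1.0):
        raise ValueError(f"explained_fraction must be in (0, 1], got {explained_fraction}")
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("data has zero variance; nothing to reduce")
    frac = np.cumsum(var) / total
    m = int(np.searchsorted(frac, explained_fraction - 1e-12) + 1)
    m = min(m, U.shape[1])
    basis = U[:, :m]
    reduction = PcaReduction(basis=basis, explained_fraction=float(frac[m - 1]))
    return basis.T @ X, reduction
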