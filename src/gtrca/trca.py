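"""Single-subject task-related component analysis (TRCA).

TRCA finds a spatial filter ``w`` maximizing the trial-to-trial
reproducibility of the component ``y = w^T X``: it maximizes ``w^T S w``
subject to ``w^T Q w = 1``, where ``S`` is the inter-trial cross-covariance
averaged over distinct trial pairs and ``Q`` the covariance of the
continuous data.  This is a generalized eigenvalue problem ``S w = λ Q w``;
the dominant eigenvalue λ₁ is itself the reproducibility of the extracted
component.

``S`` is computed in the K-sum form

    S = K / ((K-1) τ) * (U U^T - V / K),
    U = mean_k X^(k),   V = mean_k X^(k) X^(k)^T,

which is algebraically identical to the average over the K(K-1) ordered
trial pairs but much cheaper.  Because of the ``-V/K`` term, S is indefinite
and can have negative eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datasets import EpochSet, _as_float_matrix

__all__ = [
    "TrcaModel",
    "intertrial_covariance",
    "data_covariance",
    "fit_trca",
    "fit_trca_epochs",
    "fit_sign_fixed_trca",
    "project",
    "scalp_map",
    "fix_sign",
    "solve_gevp",
    "regularize_spd",
]

#: ridge strength relative to mean diagonal, applied when Q is ill-conditioned
RIDGE_EPS = 1e-9
#: condition-number threshold above which the ridge is applied
COND_MAX = 1e10


@dataclass
class TrcaModel:
    """Fitted TRCA filter(s) for one subject.

    ``w`` is the principal filter, normalized to ``w^T Q w = 1``;
    ``map`` is the corresponding scalp pattern ``Q w``.
    """

    w: np.ndarray
    eigenvalues: np.ndarray  # all generalized eigenvalues, descending
    all_filters: np.ndarray  # (n, n_components), Q-normalized columns
    S: np.ndarray
    Q: np.ndarray
    map: np.ndarray

    @property
    def lambda1(self) -> float:
        return float(self.eigenvalues[0])


def _summaries(trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    U = trials.mean(axis=0)
    V = np.einsum("knt,kmt->nm", trials, trials) / trials.shape[0]
    return U, (V + V.T) / 2.0


def intertrial_covariance(epochs: EpochSet) -> np.ndarray:
    """Inter-trial cross-covariance S, averaged over distinct trial pairs."""
    K = epochs.K
    if K < 2:
        raise ValueError("inter-trial covariance needs at least 2 trials")
    tau = epochs.tau
    U, V = _summaries(epochs.trials)
    S = K / ((K - 1) * tau) * (U @ U.T - V / K)
    return (S + S.T) / 2.0


def data_covariance(X: np.ndarray) -> np.ndarray:
    """Covariance of the continuous data, Q = X X^T / T (population)."""
    X = _as_float_matrix(X)
    T = X.shape[1]
    if T < 2:
        raise ValueError("need at least 2 samples")
    Q = X @ X.T / T
    return (Q + Q.T) / 2.0


def regularize_spd(Q: np.ndarray, eps: float = RIDGE_EPS, cond_max: float = COND_MAX) -> np.ndarray:
    """Return Q with a small ridge added if it is ill-conditioned.

    The ridge is ``eps * trace(Q)/n`` on the diagonal, applied only when the
    condition number exceeds ``cond_max`` (or Q is not positive definite).
    """
    Q = (Q + Q.T) / 2.0
    ev = np.linalg.eigvalsh(Q)
    lo, hi = ev[0], ev[-1]
    if hi <= 0:
        raise np.linalg.LinAlgError("covariance matrix has no positive eigenvalues")
    if lo <= 0 or hi / lo > cond_max:
        Q = Q + (eps * np.trace(Q) / Q.shape[0]) * np.eye(Q.shape[0])
        ev = np.linalg.eigvalsh(Q)
        lo, hi = ev[0], ev[-1]
        if lo <= 0 or hi / lo > 1.0 / np.finfo(float).eps:
            raise np.linalg.LinAlgError(
                "covariance matrix is numerically singular even after ridge "
                "regularization; reduce dimensionality first (see reduce_dimensions)"
            )
    return Q


def solve_gevp(S: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve S w = λ Q w for symmetric S and SPD (after regularization) Q.

    Returns (eigenvalues descending, eigenvectors as columns) with each
    eigenvector normalized to ``w^T Q w = 1``.  Ties between eigenvalues are
    left in solver order (they only arise for degenerate inputs).
    """
    S = (np.asarray(S, float) + np.asarray(S, float).T) / 2.0
    Qr = regularize_spd(np.asarray(Q, float))
    vals, vecs = linalg.eigh(S, Qr)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def fit_trca(S: np.ndarray, Q: np.ndarray, n_components: int = 1) -> TrcaModel:
    """Fit TRCA from precomputed S and Q matrices.

    By default only the principal eigenvector is retained; the remaining
    eigenvalues are still reported as the reproducibility spectrum.
    """
    vals, vecs = solve_gevp(S, Q)
    n_components = int(n_components)
    if not (1 <= n_components <= vecs.shape[1]):
        raise ValueError(f"n_components must be in [1, {vecs.shape[1]}]")
    w = vecs[:, 0]
    Qs = (np.asarray(Q, float) + np.asarray(Q, float).T) / 2.0
    return TrcaModel(
        w=w,
        eigenvalues=vals,
        all_filters=vecs[:, :n_components],
        S=S,
        Q=Qs,
        map=Qs @ w,
    )


def fit_trca_epochs(epochs: EpochSet, X_continuous: np.ndarray | None = None, n_components: int = 1) -> TrcaModel:
    """Convenience wrapper: S from the epochs, Q from the continuous data.

    When no continuous data is supplied, the epochs are concatenated
    horizontally to stand in for it.
    """
    S = intertrial_covariance(epochs)
    if X_continuous is None:
        X_continuous = np.hstack(list(epochs.trials))
    Q = data_covariance(X_continuous)
    return fit_trca(S, Q, n_components=n_components)


def fit_sign_fixed_trca(
    epochs: EpochSet,
    X_continuous: np.ndarray | None = None,
    reference_channels: list[int] | None = None,
) -> TrcaModel:
    """Fit a single subject's TRCA and resolve the sign against the
    channel-mean of the continuous data (or a channel subset)."""
    model = fit_trca_epochs(epochs, X_continuous)
    ref = X_continuous if X_continuous is not None else np.hstack(list(epochs.trials))
    return fix_sign(model, ref, reference_channels)


def project(w: np.ndarray, data: np.ndarray | EpochSet) -> np.ndarray:
    """Apply the spatial filter: y = w^T X (continuous) or per-trial y^(k)."""
    w = np.asarray(w, dtype=np.float64)
    if isinstance(data, EpochSet):
        if data.n_channels != w.shape[0]:
            raise ValueError(
                f"filter has {w.shape[0]} weights but epochs have {data.n_channels} channels"
            )
        return np.einsum("n,knt->kt", w, data.trials)
    X = _as_float_matrix(data)
    if X.shape[0] != w.shape[0]:
        raise ValueError(f"filter has {w.shape[0]} weights but data has {X.shape[0]} channels")
    return w @ X


def scalp_map(Q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Scalp pattern of the component: Q w = X y^T / T."""
    return np.asarray(Q, dtype=np.float64) @ np.asarray(w, dtype=np.float64)


def fix_sign(
    model: TrcaModel,
    X: np.ndarray,
    reference_channels: list[int] | None = None,
) -> TrcaModel:
    """Resolve the sign ambiguity of the filter.

    The eigenvector sign is arbitrary; by convention the component is made
    positively correlated with a reference signal, the mean of the selected
    channels of ``X`` (all channels when none are given; occipital channels
    such as O1/O2/Oz are the natural choice for SSVEP data).  Eigenvalues and
    the component magnitude are unaffected.
    """
    X = _as_float_matrix(X)
    if reference_channels is None:
        ref = X.mean(axis=0)
    else:
        idx = np.asarray(reference_channels, dtype=int)
        if idx.size == 0:
            raise ValueError("reference channel set is empty")
        ref = X[idx].mean(axis=0)
    if np.std(ref) == 0:
        raise ValueError("reference signal is constant; cannot fix the sign against it")
    y = model.w @ X
    if np.std(y) == 0:
        raise ValueError("component is constant; cannot fix its sign")
    r = float(np.corrcoef(y, ref)[0, 1])
    if r < 0:
        return TrcaModel(
            w=-model.w,
            eigenvalues=model.eigenvalues,
            all_filters=np.concatenate([-model.all_filters[:, :1], model.all_filters[:, 1:]], axis=1),
            S=model.S,
            Q=model.Q,
            map=-model.map,
        )
    return model
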