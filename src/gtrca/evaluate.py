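"""Figures of merit: trial-averaged PSD and SNR, the resampling eigenvalue
test, scalp-map and component correlation summaries, and t-SNE cluster
separation.

SNR here is the fraction of one-sided, non-DC spectral power concentrated
in the bin nearest the stimulation frequency, so it lies in [0, 1]; with
the periodogram scaling used, the spectral bins of a single trial sum to
its population variance (Parseval), which makes the fraction directly
interpretable.

The resampling test asks whether the dominant group eigenvalue could have
arisen without any component time-locked to the trial onsets: surrogate
datasets redraw every subject's trial onsets uniformly at random over the
non-overlapping window placements, the group model is refitted, and the
p-value is the add-one-corrected rank of the observed eigenvalue among the
surrogates.  Overlapping placements are excluded because windows sharing
samples are spuriously reproducible, which would inflate the surrogate
eigenvalues relative to the (non-overlapping) observed trials and make the
test conservative; restricting both to non-overlapping layouts keeps
observed and surrogate statistics exchangeable under stationary noise.
The test therefore requires the recording to be longer than K*tau (some
inter-trial slack must exist).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datasets import EpochSet, GroupDataset
from .group import assemble_group_matrices, block_layout, trial_summaries, _diag_block
from .trca import data_covariance, regularize_spd, solve_gevp

__all__ = [
    "PsdResult",
    "SurrogateTestResult",
    "trial_psd",
    "snr",
    "surrogate_test",
    "map_correlation",
    "trc_correlation_matrix",
    "embedding_fdr",
    "fisher_discriminant_ratio",
]


@dataclass
class PsdResult:
    """One-sided trial-averaged periodogram."""

    freqs: np.ndarray
    power: np.ndarray
    resolution: float  # Hz per bin, fs / tau


@dataclass
class SurrogateTestResult:
    """Observed dominant eigenvalue against the onset-randomized null."""

    lambda_obs: float
    lambda_surrogates: np.ndarray
    p_value: float
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "lambda_obs": self.lambda_obs,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "lambda_surrogates": self.lambda_surrogates.tolist(),
        }


def trial_psd(trials: np.ndarray, fs: float) -> PsdResult:
    """Per-trial periodograms averaged over trials.

    ``trials`` is (K, tau) (a single series is accepted as (tau,)).  The
    scaling doubles non-DC, non-Nyquist bins so that for each trial the sum
    over all bins (including DC) equals its mean square; excluding DC it
    equals the population variance.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=np.float64))
    tau = trials.shape[1]
    if tau < 4:
        raise ValueError("need at least 4 samples per trial")
    spec = np.abs(np.fft.rfft(trials, axis=1)) ** 2 / tau**2
    spec[:, 1:] *= 2.0
    if tau % 2 == 0:
        spec[:, -1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(tau, d=1.0 / fs)
    return PsdResult(freqs=freqs, power=spec.mean(axis=0), resolution=fs / tau)


def snr(psd: PsdResult, f_stim: float) -> float:
    """Power fraction at the bin nearest ``f_stim`` over all non-DC bins."""
    nyquist = psd.freqs[-1]
    if not (psd.resolution <= f_stim <= nyquist):
        raise ValueError(
            f"f_stim={f_stim} Hz outside the resolvable range "
            f"[{psd.resolution}, {nyquist}] Hz"
        )
    k = int(np.argmin(np.abs(psd.freqs - f_stim)))
    denom = psd.power[1:].sum()
    if denom == 0:
        raise ValueError("spectrum has no non-DC power")
    return float(psd.power[k] / denom)


def _dominant_eigenvalue(S: np.ndarray, cho) -> float:
    """Largest generalized eigenvalue via a precomputed Cholesky of Q."""
    c, lower = cho
    M = linalg.solve_triangular(c, S, lower=lower, trans="T" if not lower else "N")
    M = linalg.solve_triangular(c, M.T, lower=lower, trans="T" if not lower else "N")
    N = M.shape[0]
    return float(linalg.eigh(M, eigvals_only=True, subset_by_index=[N - 1, N - 1])[0])


def surrogate_test(group: GroupDataset, B: int = 199, alpha: float = 0.05, seed: int = 0) -> SurrogateTestResult:
    """Resampling significance test of the dominant group eigenvalue.

    Null hypothesis: no reproducible component is time-locked to the trial
    onsets.  Each of the ``B`` surrogates redraws each subject's K onsets
    uniformly over the non-overlapping placements of K windows of length
    tau in [0, T] (independently per subject), keeping the continuous data
    - hence Q - fixed, and refits the group eigenproblem.
    ``p = (1 + #{λ_surr >= λ_obs}) / (B + 1)``, never zero.  Deterministic
    given (data, B, seed).
    """
    if B < 19:
        raise ValueError("need at least 19 surrogates for a meaningful p-value")
    del alpha  # significance is the caller's decision; kept for API symmetry
    tau = group.tau
    S_obs, Q, offsets, _ = assemble_group_matrices(group)
    Qr = regularize_spd(Q)
    cho = linalg.cho_factor(Qr, lower=True)
    lambda_obs = _dominant_eigenvalue(S_obs, cho)

    rng = np.random.default_rng(seed)
    N = S_obs.shape[0]
    window = np.arange(tau)
    surrogates = np.empty(B)
    A = group.A
    recs = [rec for rec, _ in group.subjects]
    Ks = [ep.K for _, ep in group.subjects]
    for a, rec in enumerate(recs):
        slack = rec.n_samples - Ks[a] * tau
        if slack <= 0:
            raise ValueError(
                "surrogate onsets need inter-trial slack: recording length "
                f"{rec.n_samples} leaves no alternative non-overlapping placement "
                f"of {Ks[a]} windows of {tau} samples"
            )
    for b in range(B):
        S = np.zeros((N, N))
        Us = []
        for a, rec in enumerate(recs):
            slack = rec.n_samples - Ks[a] * tau
            gaps = np.sort(rng.integers(0, slack + 1, size=Ks[a]))
            onsets = gaps + np.arange(Ks[a]) * tau
            W = rec.X[:, onsets[:, None] + window[None, :]].transpose(1, 0, 2)
            summ = trial_summaries(EpochSet(trials=W, fs=rec.fs))
            Us.append(summ.U)
            sl = slice(offsets[a], offsets[a + 1])
            S[sl, sl] = 2.0 * _diag_block(summ, Ks[a], tau)
        for a in range(A):
            for c in range(a + 1, A):
                blk = Us[a] @ Us[c].T / tau
                S[offsets[a]:offsets[a + 1], offsets[c]:offsets[c + 1]] = blk
                S[offsets[c]:offsets[c + 1], offsets[a]:offsets[a + 1]] = blk.T
        surrogates[b] = _dominant_eigenvalue(S, cho)
    p = (1.0 + np.count_nonzero(surrogates >= lambda_obs)) / (B + 1.0)
    return SurrogateTestResult(
        lambda_obs=lambda_obs,
        lambda_surrogates=surrogates,
        p_value=float(p),
        B=B,
        seed=seed,
    )


def map_correlation(maps: list[np.ndarray]) -> tuple[np.ndarray, float, float]:
    """Pairwise Pearson correlations between scalp maps.

    Returns the full correlation matrix plus the mean and SD over the
    off-diagonal (unordered) pairs - the spatial-reproducibility summary.
    """
    M = np.asarray(maps, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need at least 2 maps of equal length")
    if np.any(M.std(axis=1) == 0):
        raise ValueError("constant map has undefined correlation")
    R = np.corrcoef(M)
    iu = np.triu_indices(M.shape[0], k=1)
    return R, float(R[iu].mean()), float(R[iu].std())


def trc_correlation_matrix(mean_trcs: list[np.ndarray]) -> np.ndarray:
    """Pearson correlation matrix between condition-mean components."""
    Y = np.asarray(mean_trcs, dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("mean TRCs must share the same length")
    if np.any(Y.std(axis=1) == 0):
        raise ValueError("constant component has undefined correlation")
    return np.corrcoef(Y)


def fisher_discriminant_ratio(points: np.ndarray, labels: np.ndarray) -> float:
    """trace(between-class scatter) / trace(within-class scatter).

    Returns ``inf`` when the within-class scatter vanishes but classes are
    separated (degenerate, perfectly tight clusters).
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 members")
    mu = points.mean(axis=0)
    sb = 0.0
    sw = 0.0
    for cls, nc in zip(classes, counts):
        pts = points[labels == cls]
        mc = pts.mean(axis=0)
        sb += nc * float(np.sum((mc - mu) ** 2))
        sw += float(np.sum((pts - mc) ** 2))
    if sw == 0.0:
        return float("inf") if sb > 0 else 0.0
    return sb / sw


def embedding_fdr(
    trial_trcs: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
) -> tuple[np.ndarray, float]:
    """2-D t-SNE embedding of single-trial components plus its cluster
    separation (Fisher's discriminant ratio).

    t-SNE is stochastic; the seed fixes the embedding.  Only order
    relations between FDR values of different pipelines are meaningful.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(trial_trcs, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise ValueError("trial_trcs must be (N, tau) with one label per row")
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"need more than 3*perplexity = {3 * perplexity:.0f} trials, got {X.shape[0]}"
        )
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(X)
    return emb, fisher_discriminant_ratio(emb, labels)
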