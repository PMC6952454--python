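"""Group TRCA: joint reproducibility and inter-subject similarity maximization.

Subject-specific filters ``w_α`` are stacked into one vector of length
``Σ_α n_α`` and obtained as the dominant generalized eigenvector of the
block matrices

    S = [[2 S_11, S_12, ...],          Q = blkdiag(Q_1, ..., Q_A)
         [S_21, 2 S_22, ...], ...]

where the diagonal blocks are each subject's inter-trial covariance (with
an explicit factor 2 on the diagonal, so the quadratic form ``w^T S w / 2``
splits into within-subject reproducibility plus between-subject similarity),
and the off-diagonal blocks couple trial means of different subjects:

    S_αβ = U_α U_β^T / τ   (α ≠ β),
    S_αα = K_α / ((K_α - 1) τ) * (U_α U_α^T - V_α / K_α).

With a single subject the problem reduces to TRCA with eigenvalues scaled
by exactly 2; zeroing the off-diagonal blocks decouples the problem into
the per-subject TRCA problems.

Channel counts and trial counts may differ between subjects; only the trial
length τ must be shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import EpochSet, GroupDataset
from .trca import _summaries, data_covariance, solve_gevp

__all__ = [
    "SubjectSummaries",
    "GtrcaModel",
    "trial_summaries",
    "assemble_group_matrices",
    "fit_gtrca",
    "extract_trcs",
    "block_layout",
]


@dataclass
class SubjectSummaries:
    """Per-subject trial summaries: mean U = mean_k X^(k) (n x τ) and
    scatter V = mean_k X^(k) X^(k)^T (n x n)."""

    U: np.ndarray
    V: np.ndarray


@dataclass
class GtrcaModel:
    """Fitted group model.

    ``filters[α]`` is subject α's spatial filter (the α-th block of the
    stacked dominant eigenvector, which is normalized so that
    ``stacked_w^T Q_block stacked_w = 1``).  ``maps[α] = Q_α w_α`` is the
    corresponding scalp pattern, ``mean_trcs[α] = w_α^T U_α`` the subject's
    trial-mean component, and ``group_mean_trc`` their average.
    """

    filters: list[np.ndarray]
    stacked_w: np.ndarray
    eigenvalues: np.ndarray
    S_block: np.ndarray
    Q_block: np.ndarray
    maps: list[np.ndarray]
    mean_trcs: list[np.ndarray]
    group_mean_trc: np.ndarray
    offsets: np.ndarray  # block offsets into the stacked vector, length A+1
    summaries: list[SubjectSummaries]

    @property
    def A(self) -> int:
        return len(self.filters)

    @property
    def lambda1(self) -> float:
        return float(self.eigenvalues[0])


def block_layout(channel_counts: list[int]) -> np.ndarray:
    """Offsets of each subject's block in the stacked vector (length A+1)."""
    return np.concatenate([[0], np.cumsum(np.asarray(channel_counts, dtype=np.int64))])


def trial_summaries(epochs: EpochSet) -> SubjectSummaries:
    """Trial mean and scatter for one subject."""
    U, V = _summaries(epochs.trials)
    return SubjectSummaries(U=U, V=V)


def _diag_block(summ: SubjectSummaries, K: int, tau: int) -> np.ndarray:
    if K < 2:
        raise ValueError("inter-trial covariance needs at least 2 trials per subject")
    S = K / ((K - 1) * tau) * (summ.U @ summ.U.T - summ.V / K)
    return (S + S.T) / 2.0


def assemble_group_matrices(
    group: GroupDataset,
    intersubject: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[SubjectSummaries]]:
    """Build the stacked (S, Q) matrices for the group eigenproblem.

    With ``intersubject=False`` the off-diagonal (similarity) blocks are set
    to zero; the eigenproblem then decouples into per-subject TRCA problems
    ("TRCA mode", useful as a baseline).

    Returns ``(S_block, Q_block, offsets, summaries)``.
    """
    tau = group.tau
    summaries = [trial_summaries(ep) for _, ep in group.subjects]
    Ks = [ep.K for _, ep in group.subjects]
    ns = group.channel_counts()
    offsets = block_layout(ns)
    N = int(offsets[-1])
    S = np.zeros((N, N))
    Q = np.zeros((N, N))
    for a, ((rec, _), summ) in enumerate(zip(group.subjects, summaries)):
        sl = slice(offsets[a], offsets[a + 1])
        S[sl, sl] = 2.0 * _diag_block(summ, Ks[a], tau)
        Q[sl, sl] = data_covariance(rec.X)
    if intersubject:
        for a in range(group.A):
            for b in range(a + 1, group.A):
                blk = summaries[a].U @ summaries[b].U.T / tau
                S[offsets[a]:offsets[a + 1], offsets[b]:offsets[b + 1]] = blk
                S[offsets[b]:offsets[b + 1], offsets[a]:offsets[a + 1]] = blk.T
    return S, Q, offsets, summaries


def fit_gtrca(
    group: GroupDataset,
    n_components: int = 1,
    intersubject: bool = True,
    fix_global_sign: bool = True,
) -> GtrcaModel:
    """Fit the group model: dominant eigenvector of (S_block, Q_block).

    The solution is defined up to one global sign (independent per-subject
    flips would change the inter-subject similarity term and are not
    applied).  The global sign is chosen so that the subject components are,
    on balance, positively correlated with each subject's channel-mean
    signal; set ``fix_global_sign=False`` to keep the solver's sign.
    """
    del n_components  # spectrum is returned in full; filters use the dominant one
    S, Q, offsets, summaries = assemble_group_matrices(group, intersubject=intersubject)
    vals, vecs = solve_gevp(S, Q)
    w = vecs[:, 0]

    filters = [w[offsets[a]:offsets[a + 1]] for a in range(group.A)]
    if fix_global_sign:
        score = 0.0
        for (rec, _), summ, wa in zip(group.subjects, summaries, filters):
            ya = wa @ summ.U
            ref = summ.U.mean(axis=0)
            if np.std(ya) > 0 and np.std(ref) > 0:
                score += float(np.corrcoef(ya, ref)[0, 1])
        if score < 0:
            w = -w
            filters = [-f for f in filters]

    maps = []
    for a, (rec, _) in enumerate(group.subjects):
        sl = slice(offsets[a], offsets[a + 1])
        maps.append(Q[sl, sl] @ filters[a])
    mean_trcs = [wa @ summ.U for wa, summ in zip(filters, summaries)]
    group_mean = np.mean(mean_trcs, axis=0)
    return GtrcaModel(
        filters=filters,
        stacked_w=w,
        eigenvalues=vals,
        S_block=S,
        Q_block=Q,
        maps=maps,
        mean_trcs=mean_trcs,
        group_mean_trc=group_mean,
        offsets=offsets,
        summaries=summaries,
    )


def extract_trcs(model: GtrcaModel, group: GroupDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial components for every subject.

    Returns ``(trcs, means, group_mean)`` where ``trcs`` has shape
    (A, K, τ) (requires equal trial counts), ``means`` is (A, τ) and
    ``group_mean`` is (τ,).
    """
    if model.A != group.A:
        raise ValueError(f"model has {model.A} subjects but dataset has {group.A}")
    Ks = {ep.K for _, ep in group.subjects}
    if len(Ks) != 1:
        raise ValueError("extract_trcs as an array requires equal trial counts; got " + str(sorted(Ks)))
    trcs = []
    for wa, (_, ep) in zip(model.filters, group.subjects):
        if wa.shape[0] != ep.n_channels:
            raise ValueError(
                f"filter length {wa.shape[0]} does not match {ep.n_channels} channels"
            )
        trcs.append(np.einsum("n,knt->kt", wa, ep.trials))
    trcs = np.asarray(trcs)
    means = trcs.mean(axis=1)
    return trcs, means, means.mean(axis=0)


def group_objective(trcs: np.ndarray, tau: int) -> float:
    """Recompute the eigenvalue from the components themselves.

    Evaluates ``w^T S w`` as the sum of within-subject pairwise trial
    covariances (each pair counted twice, matching the factor-2 diagonal)
    plus between-subject covariances of trial means, all divided by τ.
    Useful as a consistency check: equals λ₁ when the filters are the
    fitted, Q-normalized solution.
    """
    A, K, _ = trcs.shape
    total = 0.0
    for a in range(A):
        g = trcs[a] @ trcs[a].T  # (K, K) Gram matrix of trials
        within = (g.sum() - np.trace(g)) / (K * (K - 1) * tau)
        total += 2.0 * within
    means = trcs.mean(axis=1)
    for a in range(A):
        for b in range(A):
            if a != b:
                total += float(means[a] @ means[b]) / tau
    return total
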