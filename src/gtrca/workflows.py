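"""End-to-end study pipelines built from the library primitives.

These are the canned analyses a user runs on synthetic data to validate the
method: ground-truth parameter recovery, type-I error calibration of the
resampling test, leave-one-subject-out zero-training transfer, and the
three-way comparison (group filters vs per-subject filters vs best single
channel) in SNR and embedding cluster separation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datasets import GroupDataset
from .evaluate import (
    embedding_fdr,
    snr,
    surrogate_test,
    trial_psd,
)
from .group import extract_trcs, fit_gtrca
from .predict import predict_condition, predictive_filter
from .simulate import SyntheticParams, benchmark_params, generate_group_ssvep, generate_null
from .trca import data_covariance, fit_sign_fixed_trca

__all__ = [
    "parameter_recovery",
    "type_i_error_rate",
    "transfer_benchmark",
    "method_comparison",
    "null_test_params",
]


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(abs(np.corrcoef(a, b)[0, 1]))


def parameter_recovery(params: SyntheticParams | None = None) -> dict:
    """Fit the group model on synthetic data and score ground-truth recovery.

    Returns the per-condition correlation between the group-mean component
    and the true source, and the per-subject/condition correlation between
    the scalp map and the true mixing topography (absolute values; the
    global sign of the solution is arbitrary).
    """
    datasets, truth = generate_group_ssvep(params)
    trc_corrs = []
    map_corrs = []
    for c, group in enumerate(datasets):
        model = fit_gtrca(group)
        trc_corrs.append(_abs_corr(model.group_mean_trc, truth.sources[c]))
        map_corrs.append([_abs_corr(m, truth.mixing[a]) for a, m in enumerate(model.maps)])
    return {
        "trc_corr": np.asarray(trc_corrs),
        "map_corr": np.asarray(map_corrs),
        "min_trc_corr": float(np.min(trc_corrs)),
        "min_map_corr": float(np.min(map_corrs)),
    }


def null_test_params(seed: int = 0) -> SyntheticParams:
    """Reduced-scale pure-noise configuration for calibration studies:
    3 subjects, 8 trials of 0.4 s (0.2 s inter-trial interval) at 100 Hz
    over 6 channels, one condition.  The inter-trial interval leaves the
    onset-randomization test room to place surrogate windows."""
    return SyntheticParams(
        A=3, K=8, C=1, n=6, fs=100.0, tau_seconds=0.4, iti_seconds=0.2,
        f_start=8.0, f_step=0.0, snr=0.0, noise_spatial_rank=3, seed=seed,
    )


def type_i_error_rate(
    n_replicates: int = 200,
    B: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical rejection rate of the resampling test on pure-noise groups.

    Each replicate generates an independent null dataset and runs the test
    with ``B`` surrogates; a calibrated test rejects a fraction ~alpha of
    the time.
    """
    rejections = 0
    for i in range(n_replicates):
        params = null_test_params(seed=(seed + 1000 * i) % (2**31 - 1))
        group = generate_null(params)[0]
        res = surrogate_test(group, B=B, seed=(seed + 7 * i + 3) % (2**31 - 1))
        if res.p_value <= alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "B": B,
        "alpha": alpha,
    }


def _drop_subject(group: GroupDataset, a: int) -> GroupDataset:
    return GroupDataset(
        subjects=[s for i, s in enumerate(group.subjects) if i != a],
        condition=group.condition,
    )


def transfer_benchmark(
    params: SyntheticParams | None = None,
    n_prediction_trials: int = 50,
    seed: int = 0,
) -> dict:
    """Leave-one-subject-out zero-training condition prediction.

    For each held-out (subject, condition, trial) combination, the group
    models are fitted without that subject, the predictive filter is built
    from the single unlabeled trial (its own covariance stands in for the
    new subject's continuous covariance), and the condition with the
    highest component correlation wins.  Also scores, for one held-out
    subject, how diagonal the correlation matrix between predicted and
    full-fit components is across conditions.
    """
    params = params or benchmark_params(seed=seed)
    datasets, _ = generate_group_ssvep(params)
    A, C, K = params.A, params.C, params.K

    combos = [(a, c, (a + c) % K) for a in range(A) for c in range(C)]
    combos = combos[:n_prediction_trials]
    needed_subjects = sorted({a for a, _, _ in combos})

    loo_models = {
        a: [fit_gtrca(_drop_subject(datasets[c], a)) for c in range(C)]
        for a in needed_subjects
    }

    hits = 0
    for a, c, k in combos:
        trial = datasets[c].subjects[a][1].trials[k]
        Q_new = data_covariance(trial)
        res = predict_condition(loo_models[a], trial, Q_new)
        hits += int(res.predicted_condition == c)
    n_pred = len(combos)
    accuracy = hits / n_pred
    p_binom = stats.binomtest(hits, n_pred, p=1.0 / C, alternative="greater").pvalue

    # predicted vs full-fit components across conditions, for held-out subject 0
    full_models = [fit_gtrca(datasets[c]) for c in range(C)]
    a0 = 0
    pred_trcs = []
    for c in range(C):
        trial = datasets[c].subjects[a0][1].trials[0]
        w = predictive_filter(loo_models[a0][c], None, trial, data_covariance(trial))
        pred_trcs.append(w @ trial)
    M = np.empty((C, C))
    for c in range(C):
        for d in range(C):
            M[c, d] = abs(np.corrcoef(pred_trcs[c], full_models[d].mean_trcs[a0])[0, 1])
    diag = float(np.mean(np.diag(M)))
    off = float((M.sum() - np.trace(M)) / (C * (C - 1)))
    return {
        "accuracy": accuracy,
        "n_predictions": n_pred,
        "chance": 1.0 / C,
        "binomial_p": float(p_binom),
        "corr_matrix": M,
        "diag_mean": diag,
        "offdiag_mean": off,
        "diag_minus_offdiag": diag - off,
    }


def _mean_snr(trial_series_by_condition: list[np.ndarray], freqs: np.ndarray, fs: float) -> float:
    vals = []
    for series, f in zip(trial_series_by_condition, freqs):
        psd = trial_psd(series, fs)
        vals.append(snr(psd, float(f)))
    return float(np.mean(vals))


def _best_channel(datasets: list[GroupDataset], freqs: np.ndarray, fs: float) -> int:
    """Channel whose trial-averaged spectrum concentrates most power at the
    stimulation frequencies (the synthetic analogue of picking Oz)."""
    n = datasets[0].subjects[0][1].n_channels
    scores = np.zeros(n)
    for ds, f in zip(datasets, freqs):
        for ch in range(n):
            series = np.concatenate([ep.trials[:, ch, :] for _, ep in ds.subjects])
            scores[ch] += snr(trial_psd(series, fs), float(f))
    return int(np.argmax(scores))


def method_comparison(
    params: SyntheticParams | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
) -> dict:
    """Compare group filters, per-subject filters, and the best single
    channel on the same synthetic group: mean SNR of single-trial
    components, and t-SNE cluster separation (Fisher ratio) of single
    trials labeled by condition.

    Single-trial series are z-scored before embedding so that cluster
    structure reflects waveform shape rather than per-subject amplitude.
    """
    params = params or benchmark_params(seed=seed)
    datasets, _ = generate_group_ssvep(params)
    freqs = params.frequencies()
    fs = params.fs

    gtrca_series = []   # per condition: (A*K, tau)
    trca_series = []
    for ds in datasets:
        model = fit_gtrca(ds)
        trcs, _, _ = extract_trcs(model, ds)
        gtrca_series.append(trcs.reshape(-1, ds.tau))
        per_subj = []
        for rec, ep in ds.subjects:
            m = fit_sign_fixed_trca(ep, rec.X)
            per_subj.append(np.einsum("n,knt->kt", m.w, ep.trials))
        trca_series.append(np.concatenate(per_subj))

    ch = _best_channel(datasets, freqs, fs)
    chan_series = [
        np.concatenate([ep.trials[:, ch, :] for _, ep in ds.subjects])
        for ds in datasets
    ]

    out = {
        "snr_gtrca": _mean_snr(gtrca_series, freqs, fs),
        "snr_trca": _mean_snr(trca_series, freqs, fs),
        "snr_channel": _mean_snr(chan_series, freqs, fs),
        "best_channel": ch,
    }

    labels = np.concatenate([
        np.full(s.shape[0], c) for c, s in enumerate(gtrca_series)
    ])

    def _fdr(series_list: list[np.ndarray]) -> float:
        X = np.concatenate(series_list)
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        _, fdr = embedding_fdr(X, labels, seed=seed, perplexity=perplexity)
        return fdr

    out["fdr_gtrca"] = _fdr(gtrca_series)
    out["fdr_trca"] = _fdr(trca_series)
    out["fdr_channel"] = _fdr(chan_series)
    return out
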