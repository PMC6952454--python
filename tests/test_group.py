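import numpy as np
import pytest

from gtrca.datasets import EpochSet, GroupDataset, SubjectRecording, epoch
from gtrca.group import (
    assemble_group_matrices,
    block_layout,
    extract_trcs,
    fit_gtrca,
    group_objective,
    trial_summaries,
)
from gtrca.simulate import SyntheticParams, generate_group_ssvep
from gtrca.trca import fit_trca_epochs, intertrial_covariance, solve_gevp


def brute_force_cross_block(trials_a, trials_b):
    """Eq.-style double sum over all K*K trial pairs of two subjects."""
    K, _, tau = trials_a.shape
    S = np.zeros((trials_a.shape[1], trials_b.shape[1]))
    for k in range(K):
        for l in range(K):
            S += trials_a[k] @ trials_b[l].T
    return S / (K * K * tau)


def _group_from_trials(trials_list, fs=100.0):
    subjects = []
    for i, tr in enumerate(trials_list):
        X = np.hstack(list(tr))
        rec = SubjectRecording(f"s{i}", X, fs, np.arange(tr.shape[0]) * tr.shape[2], tr.shape[2])
        subjects.append((rec, epoch(rec)))
    from gtrca.datasets import ConditionInfo

    return GroupDataset(subjects=subjects, condition=ConditionInfo(0, 10.0))


class TestTrialSummaries:
    def test_single_trial(self, rng):
        X = rng.standard_normal((3, 10))
        s = trial_summaries(EpochSet(trials=X[None], fs=100.0))
        assert np.array_equal(s.U, X)
        assert np.allclose(s.V, X @ X.T)

    def test_plus_minus_cancellation(self, rng):
        M = rng.standard_normal((2, 8))
        s = trial_summaries(EpochSet(trials=np.stack([M, -M]), fs=100.0))
        assert np.max(np.abs(s.U)) < 1e-15
        assert np.allclose(s.V, M @ M.T)

    def test_matches_explicit_loop(self, rng):
        trials = rng.standard_normal((4, 3, 12))
        s = trial_summaries(EpochSet(trials=trials, fs=100.0))
        U = sum(trials[k] for k in range(4)) / 4
        V = sum(trials[k] @ trials[k].T for k in range(4)) / 4
        assert np.max(np.abs(s.U - U)) < 1e-13
        assert np.max(np.abs(s.V - V)) < 1e-13


class TestAssemble:
    def test_single_subject_diagonal_factor_two(self, rng):
        trials = rng.standard_normal((3, 4, 10))
        g = _group_from_trials([trials])
        S, Q, offsets, _ = assemble_group_matrices(g)
        S_single = intertrial_covariance(g.subjects[0][1])
        assert np.max(np.abs(S - 2.0 * S_single)) < 1e-12
        assert np.array_equal(offsets, [0, 4])

    def test_identical_subjects_symmetric_blocks(self, rng):
        trials = rng.standard_normal((3, 4, 10))
        g = _group_from_trials([trials, trials.copy()])
        S, _, off, summ = assemble_group_matrices(g)
        S12 = S[0:4, 4:8]
        assert np.allclose(S12, summ[0].U @ summ[0].U.T / 10)
        assert np.allclose(S12, S[4:8, 0:4].T)

    def test_off_diagonal_matches_double_sum(self, rng):
        ta = rng.standard_normal((3, 4, 9))
        tb = rng.standard_normal((3, 4, 9))
        g = _group_from_trials([ta, tb])
        S, _, _, _ = assemble_group_matrices(g)
        assert np.max(np.abs(S[0:4, 4:8] - brute_force_cross_block(ta, tb))) < 1e-12

    def test_block_structure_and_symmetry(self, rng):
        trials = [rng.standard_normal((3, 4, 10)) for _ in range(3)]
        g = _group_from_trials(trials)
        S, Q, _, _ = assemble_group_matrices(g)
        assert S.shape == (12, 12)
        assert np.max(np.abs(S - S.T)) < 1e-12
        assert np.max(np.abs(Q[0:4, 4:8])) == 0.0  # Q is block diagonal

    def test_layout_for_benchmark_shape(self):
        assert block_layout([64] * 35)[-1] == 2240

    def test_mismatched_tau_rejected(self, rng):
        from gtrca.datasets import ConditionInfo

        r1 = SubjectRecording("a", rng.standard_normal((2, 20)), 100.0, [0, 10], 10)
        r2 = SubjectRecording("b", rng.standard_normal((2, 16)), 100.0, [0, 8], 8)
        with pytest.raises(ValueError, match="tau"):
            GroupDataset(subjects=[(r1, epoch(r1)), (r2, epoch(r2))],
                         condition=ConditionInfo(0, 10.0))


class TestFitGtrca:
    def test_single_subject_reduces_to_trca(self, rng):
        trials = rng.standard_normal((4, 5, 20))
        g = _group_from_trials([trials])
        gm = fit_gtrca(g, fix_global_sign=False)
        tm = fit_trca_epochs(g.subjects[0][1], g.subjects[0][0].X)
        assert np.max(np.abs(gm.eigenvalues - 2.0 * tm.eigenvalues)) < 1e-9
        dev = min(np.max(np.abs(gm.filters[0] - tm.w)), np.max(np.abs(gm.filters[0] + tm.w)))
        assert dev < 1e-8

    def test_decoupled_mode_recovers_per_subject_trca(self, rng):
        trials = [rng.standard_normal((4, 3, 15)) for _ in range(2)]
        g = _group_from_trials(trials)
        S, Q, off, _ = assemble_group_matrices(g, intersubject=False)
        vals, vecs = solve_gevp(S, Q)
        for a in range(2):
            sl = slice(off[a], off[a + 1])
            other = np.delete(np.arange(6), np.arange(off[a], off[a + 1]))
            in_block = np.linalg.norm(vecs[sl], axis=0)
            out_block = np.linalg.norm(vecs[other], axis=0)
            # eigenpairs supported on this block; take the dominant one
            mask = out_block < 1e-8 * np.maximum(in_block, 1e-30) + 1e-10
            idx = np.flatnonzero(mask)
            j = idx[np.argmax(vals[idx])]
            tm = fit_trca_epochs(g.subjects[a][1], g.subjects[a][0].X)
            assert abs(vals[j] - 2.0 * tm.lambda1) < 1e-9
            wa = vecs[sl, j]
            dev = min(np.max(np.abs(wa - tm.w)), np.max(np.abs(wa + tm.w)))
            assert dev < 1e-7

    def test_stacked_normalization(self, small_group):
        _, datasets, _ = small_group
        m = fit_gtrca(datasets[0])
        assert abs(m.stacked_w @ m.Q_block @ m.stacked_w - 1.0) < 1e-8

    def test_permutation_equivariance(self, small_group):
        _, datasets, _ = small_group
        g = datasets[0]
        m = fit_gtrca(g, fix_global_sign=False)
        perm = [2, 0, 1]
        gp = GroupDataset(subjects=[g.subjects[i] for i in perm], condition=g.condition)
        mp = fit_gtrca(gp, fix_global_sign=False)
        for new_pos, old_pos in enumerate(perm):
            dev = min(
                np.max(np.abs(mp.filters[new_pos] - m.filters[old_pos])),
                np.max(np.abs(mp.filters[new_pos] + m.filters[old_pos])),
            )
            assert dev < 1e-7

    def test_per_subject_scale_invariance(self, small_group):
        _, datasets, _ = small_group
        g = datasets[0]
        m = fit_gtrca(g, fix_global_sign=False)
        scaled = []
        for i, (rec, _) in enumerate(g.subjects):
            c = 3.0 if i == 1 else 1.0
            nr = SubjectRecording(rec.subject_id, c * rec.X, rec.fs, rec.onsets, rec.tau)
            scaled.append((nr, epoch(nr)))
        ms = fit_gtrca(GroupDataset(subjects=scaled, condition=g.condition),
                       fix_global_sign=False)
        y = np.concatenate(m.mean_trcs)
        ys = np.concatenate(ms.mean_trcs)
        assert min(np.max(np.abs(y - ys)), np.max(np.abs(y + ys))) < 1e-7


class TestExtractTrcs:
    def test_means_and_shapes(self, small_group):
        _, datasets, _ = small_group
        g = datasets[0]
        m = fit_gtrca(g)
        trcs, means, gmean = extract_trcs(m, g)
        assert trcs.shape == (g.A, g.subjects[0][1].K, g.tau)
        for a in range(g.A):
            assert np.max(np.abs(means[a] - m.filters[a] @ m.summaries[a].U)) < 1e-12
        assert np.max(np.abs(gmean - m.group_mean_trc)) < 1e-12

    def test_lambda_recovered_from_components(self, small_group):
        _, datasets, _ = small_group
        g = datasets[0]
        m = fit_gtrca(g)
        trcs, _, _ = extract_trcs(m, g)
        assert abs(group_objective(trcs, g.tau) - m.lambda1) < 1e-8
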