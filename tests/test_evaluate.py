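import numpy as np
import pytest

from gtrca.evaluate import (
    PsdResult,
    embedding_fdr,
    fisher_discriminant_ratio,
    map_correlation,
    snr,
    surrogate_test,
    trc_correlation_matrix,
    trial_psd,
)
from gtrca.simulate import SyntheticParams, generate_group_ssvep, generate_null
from gtrca.workflows import null_test_params


def dft_loop_psd(x):
    """Independent periodogram oracle: explicit DFT sums."""
    tau = len(x)
    n_bins = tau // 2 + 1
    p = np.zeros(n_bins)
    t = np.arange(tau)
    for j in range(n_bins):
        re = np.sum(x * np.cos(2 * np.pi * j * t / tau))
        im = np.sum(x * np.sin(2 * np.pi * j * t / tau))
        p[j] = (re**2 + im**2) / tau**2
        if 0 < j and not (tau % 2 == 0 and j == n_bins - 1):
            p[j] *= 2
    return p


class TestTrialPsd:
    def test_bin_aligned_sinusoid_single_bin(self):
        fs, tau = 100.0, 200
        t = np.arange(tau) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        psd = trial_psd(x, fs)
        k = np.argmin(np.abs(psd.freqs - 10.0))
        rest = np.delete(psd.power, k)
        assert np.all(rest < 1e-10 * psd.power[k])

    def test_parseval(self, rng):
        x = rng.standard_normal(128)
        psd = trial_psd(x, 100.0)
        assert abs(psd.power[1:].sum() - x.var()) < 1e-10
        assert abs(psd.power.sum() - (x**2).mean()) < 1e-10

    @pytest.mark.parametrize("tau", [32, 33])
    def test_matches_dft_loop_oracle(self, rng, tau):
        x = rng.standard_normal(tau)
        psd = trial_psd(x, 50.0)
        assert np.max(np.abs(psd.power - dft_loop_psd(x))) < 1e-10

    def test_averages_over_trials(self, rng):
        trials = rng.standard_normal((5, 64))
        psd = trial_psd(trials, 100.0)
        single = np.mean([trial_psd(t, 100.0).power for t in trials], axis=0)
        assert np.max(np.abs(psd.power - single)) < 1e-12


class TestSnr:
    def test_noiseless_sinusoid_is_one(self):
        fs, tau = 100.0, 200
        x = np.sin(2 * np.pi * 12.0 * np.arange(tau) / fs)
        assert abs(snr(trial_psd(x, fs), 12.0) - 1.0) < 1e-10

    def test_flat_spectrum_is_one_over_m(self):
        freqs = np.arange(0, 11) * 1.0
        power = np.ones(11)
        psd = PsdResult(freqs=freqs, power=power, resolution=1.0)
        assert abs(snr(psd, 5.0) - 1.0 / 10.0) < 1e-12  # 10 non-DC bins

    def test_out_of_range_raises(self):
        psd = trial_psd(np.sin(np.arange(100.0)), 100.0)
        with pytest.raises(ValueError, match="outside"):
            snr(psd, 60.0)

    def test_monotone_in_noise(self):
        fs, tau = 100.0, 200
        t = np.arange(tau) / fs
        rng = np.random.default_rng(0)
        noise = rng.standard_normal((8, tau))
        vals = []
        for sigma in [0.0, 0.5, 1.0, 2.0, 4.0]:
            trials = np.sin(2 * np.pi * 10.0 * t) + sigma * noise
            vals.append(snr(trial_psd(trials, fs), 10.0))
        assert np.all(np.diff(vals) < 0)


class TestSurrogateTest:
    def test_p_value_bounds_and_determinism(self):
        g = generate_null(null_test_params(seed=5))[0]
        r1 = surrogate_test(g, B=19, seed=42)
        r2 = surrogate_test(g, B=19, seed=42)
        assert 1 / 20 <= r1.p_value <= 1.0
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.lambda_surrogates, r2.lambda_surrogates)

    def test_different_seed_changes_surrogates(self):
        g = generate_null(null_test_params(seed=5))[0]
        r1 = surrogate_test(g, B=19, seed=1)
        r2 = surrogate_test(g, B=19, seed=2)
        assert not np.array_equal(r1.lambda_surrogates, r2.lambda_surrogates)

    def test_strong_signal_minimal_p(self):
        params = SyntheticParams(A=3, K=6, C=1, n=8, fs=100.0, tau_seconds=0.4,
                                 iti_seconds=0.2, snr=5.0, seed=0)
        g = generate_group_ssvep(params)[0][0]
        res = surrogate_test(g, B=99, seed=11)
        assert res.p_value == pytest.approx(1 / 100)

    def test_tiled_recording_rejected(self):
        # no inter-trial slack -> only one non-overlapping placement exists
        g = generate_null(SyntheticParams(
            A=2, K=4, C=1, n=4, fs=100.0, tau_seconds=0.4, snr=0.0, seed=0))[0]
        with pytest.raises(ValueError, match="slack"):
            surrogate_test(g, B=19, seed=0)

    def test_too_few_surrogates_rejected(self):
        g = generate_null(null_test_params(seed=0))[0]
        with pytest.raises(ValueError, match="19"):
            surrogate_test(g, B=5, seed=0)


class TestMapCorrelation:
    def test_identical_maps(self, rng):
        m = rng.standard_normal(8)
        R, mean, sd = map_correlation([m, m.copy(), m.copy()])
        assert np.allclose(R, 1.0)
        assert mean == pytest.approx(1.0)

    def test_negated_map(self, rng):
        m = rng.standard_normal(8)
        _, mean, _ = map_correlation([m, -m])
        assert mean == pytest.approx(-1.0)

    def test_structure_on_random_maps(self, rng):
        maps = list(rng.standard_normal((35, 64)))
        R, mean, sd = map_correlation(maps)
        assert R.shape == (35, 35)
        assert np.allclose(np.diag(R), 1.0)
        assert np.max(np.abs(R - R.T)) < 1e-12
        assert sd >= 0

    def test_constant_map_raises(self):
        with pytest.raises(ValueError, match="constant"):
            map_correlation([np.ones(5), np.arange(5.0)])


class TestTrcCorrelationMatrix:
    def test_identical_components(self, rng):
        y = rng.standard_normal(30)
        assert np.allclose(trc_correlation_matrix([y, y, y]), 1.0)

    def test_orthogonal_sinusoids(self):
        t = np.arange(100)
        ys = [np.sin(2 * np.pi * f * t / 100) for f in (3, 7, 11)]
        R = trc_correlation_matrix(ys)
        off = R[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-10

    def test_symmetric_unit_diagonal(self, rng):
        R = trc_correlation_matrix(list(rng.standard_normal((5, 40))))
        assert np.allclose(np.diag(R), 1.0)
        assert np.max(np.abs(R - R.T)) < 1e-12


class TestFisherDiscriminantRatio:
    def test_duplicated_points_sentinel(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0], [10.0, 10.0]])
        labels = np.array([0, 0, 1, 1])
        assert fisher_discriminant_ratio(pts, labels) == np.inf

    def test_nonnegative(self, rng):
        pts = rng.standard_normal((40, 2))
        labels = rng.integers(0, 2, 40)
        while np.unique(labels, return_counts=True)[1].min() < 2:
            labels = rng.integers(0, 2, 40)
        assert fisher_discriminant_ratio(pts, labels) >= 0

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="2 members"):
            fisher_discriminant_ratio(np.zeros((3, 2)), np.array([0, 0, 1]))


class TestEmbeddingFdr:
    def test_separated_clusters_beat_shuffled_labels(self, rng):
        tau = 40
        a = rng.standard_normal((25, tau)) + 5.0
        b = rng.standard_normal((25, tau)) - 5.0
        X = np.vstack([a, b])
        labels = np.repeat([0, 1], 25)
        _, fdr = embedding_fdr(X, labels, seed=0, perplexity=10.0)
        shuffled = rng.permutation(labels)
        while np.unique(shuffled[:25]).size < 2:  # ensure both classes occupied
            shuffled = rng.permutation(labels)
        _, fdr_shuf = embedding_fdr(X, shuffled, seed=0, perplexity=10.0)
        assert fdr >= 10.0 * fdr_shuf

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            embedding_fdr(rng.standard_normal((20, 5)), np.repeat([0, 1], 10),
                          perplexity=30.0)
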