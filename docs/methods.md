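# Methods

## Model

Single-subject task-related component analysis (TRCA) extracts a spatial
filter `w ∈ R^n` whose component `y = wᵀX` is maximally reproducible across
trials: maximize `wᵀS w` subject to `wᵀQ w = 1`, where

- `S = (1 / K(K−1)τ) Σ_{k≠ℓ} X⁽ᵏ⁾X⁽ˡ⁾ᵀ` is the inter-trial cross-covariance
  (computed in the equivalent K-sum form
  `S = K/((K−1)τ)(UUᵀ − V/K)` with `U = mean_k X⁽ᵏ⁾`,
  `V = mean_k X⁽ᵏ⁾X⁽ᵏ⁾ᵀ`), and
- `Q = XXᵀ/T` is the covariance of the continuous recording.

This is the generalized eigenproblem `S w = λ Q w`; the dominant eigenvalue
λ₁ equals the average pairwise trial covariance of the extracted component
and is therefore itself a reproducibility index. `S` is indefinite (the
`−V/K` term) and can have negative eigenvalues. The scalp pattern of a
component is `Q w` (`XyᵀT⁻¹` lifted through the filter).

The group extension (gTRCA) stacks per-subject filters `w_α` into one
vector of length `Σ_α n_α` and solves the same problem with block matrices:
off-diagonal blocks `S_αβ = U_α U_βᵀ/τ` couple the trial means of different
subjects, diagonal blocks carry each subject's inter-trial covariance with
an explicit factor 2 (so `wᵀS w / 2` decomposes into within-subject
reproducibility plus between-subject similarity), and `Q` is block-diagonal
in the per-subject data covariances. Two limits pin the conventions: with
one subject the eigenvalues are exactly twice the TRCA eigenvalues with the
same eigenvectors, and zeroing the off-diagonal blocks decouples the
problem into the per-subject TRCA problems ("TRCA mode", used as a
baseline).

The zero-training predictive filter for a new subject maximizes covariance
between the new subject's single-trial component and the group-mean
component under a unit-variance constraint, giving the closed form
`w_new ∝ Q_new⁻¹ X_new⁽¹⁾ Σ_α U_αᵀ w_α`. The Lagrange multiplier is never
computed: the raw filter is rescaled post hoc so `var(w_newᵀ X_new) = 1`
over the new subject's continuous data (the trial itself stands in when
only one trial exists). Condition prediction builds one such filter per
candidate condition and picks the condition whose group-mean component
correlates best with the projected trial.

## Numerical choices

- **Variance convention.** Population (divisor `T`) everywhere, so channel
  normalization makes `diag(Q) = 1` exactly — a testable invariant.
- **Windows.** 0-based, half-open `[t_k, t_k + τ)`.
- **Eigensolver.** `scipy.linalg.eigh(S, Q)` (symmetric-definite). When
  `cond(Q) > 1e10` or Q is not positive definite, a ridge
  `1e−9 · trace(Q)/n` is added once; if Q is still singular the solver
  raises and advises PCA reduction. Eigenvectors come back Q-normalized
  (`wᵀQw = 1`). Eigenvalue ties are left in solver order; they only occur
  for degenerate inputs.
- **Signs.** The group solution is defined up to one *global* sign only;
  independent per-subject flips would change the inter-subject similarity
  term, so they are not applied by the solver (they remain available as a
  display choice). The global sign makes the subject components, on
  balance, positively correlated with each subject's channel-mean signal.
  For per-subject TRCA the sign is fixed against the channel mean (or a
  channel subset such as the occipital electrodes for real SSVEP montages).
  With random synthetic topographies the channel-mean reference can be
  weak, which makes the TRCA baseline's cross-subject sign alignment — and
  hence its embedding cluster separation — noticeably seed-sensitive; the
  group solution does not suffer from this because relative signs are part
  of the joint eigenvector.
- **Bandpass.** Linear-phase Hamming-window FIR (length from the
  3.3/Δf rule for the requested transition band, default 1 Hz), applied
  forward–backward for zero phase so trial-locked latencies are preserved.
  The recommended order, filter → normalize → epoch, is a convention of
  this package (normalization guarantees hold for whatever enters the
  covariances last).
- **Unequal subjects.** Channel counts and trial counts may differ across
  subjects (block offsets are tracked explicitly); only the trial length τ
  must be shared, since components are compared sample by sample.

## Resampling significance test

Null hypothesis: no component is time-locked to the trial onsets. The
observed λ₁ is compared against `B` surrogates in which every subject's
onsets are redrawn and the group model refitted (Q is unchanged; only `S`
depends on the onsets, so Q is Cholesky-factorized once per test).
`p = (1 + #{λ_surr ≥ λ_obs}) / (B + 1)`, never zero.

Surrogate onsets are drawn uniformly over the **non-overlapping**
placements of K windows (stars-and-bars over the inter-trial slack).
Allowing overlaps would make windows share samples, which is spuriously
"reproducible": in calibration runs with overlap-allowed sampling the null
p-values piled up near 1 (empirical level ≈ 0 at α = 0.05). Restricting
both the observed layout and the surrogates to non-overlapping placements
restores exchangeability under stationary noise. A consequence is that the
recording must be longer than `K·τ`; on data whose trials exactly tile the
recording the test raises an error rather than returning a meaningless
p-value.

Calibration, measured on 200 independent pure-noise groups (B = 99,
α = 0.05), is within the 95% binomial band around the nominal level. The
test retains a mild conservative bias (empirical level ≈ 0.02–0.03)
because the background noise is temporally autocorrelated and surrogate
placements are on average closer together than the evenly spaced
experimental layout; a conservative test errs on the safe side.

## Synthetic data generator

The generator emulates JFPM-coded SSVEPs: condition `c` drives
`s_c(t) = Σ_h h⁻¹ sin(2π h f_c t + h φ_c)` with `f_c = f_start + c·f_step`
and `φ_c = c·phase_step`; the 1/h harmonic decay reproduces the bimodal
waveforms of low-frequency flicker responses. Each subject mixes the
source through a fixed smooth random topography (Gaussian-smoothed white
noise over the channel axis, unit norm) — abstract patterns, not a forward
head model. Noise is spatially low-rank pink background (one continuous
per-subject stream, so the null is stationary across trial boundaries)
plus per-trial white sensor noise, in RMS proportions 0.8 : 0.6; `snr` is
the per-trial signal-to-total-noise RMS amplitude ratio. Trials are
concatenated (optionally separated by an inter-trial interval) into the
continuous recording and channels are normalized, so generated epochs
slice exactly out of the recording. All randomness derives from the master
seed through fixed per-(subject, condition[, trial]) stream keys: the same
seed is byte-identical, and adding subjects or trials does not reshuffle
existing streams.

Default conditions: 5 subjects, 6 trials of 2 s at 250 Hz, 16 channels,
4 conditions from 8 Hz in 0.2 Hz / 90° steps, 3 harmonics, snr 1. The
transfer/comparison benchmark uses 10 subjects, 8 conditions at 8–15 Hz in
1 Hz steps and snr 0.5 (moderate noise); a full-scale preset mirrors the
public 35-subject / 64-channel / 40-condition benchmark geometry. The
type-I calibration study uses a deliberately reduced scale (3 subjects, 8
trials of 0.4 s at 100 Hz over 6 channels, 0.2 s inter-trial interval) so
that hundreds of replicate tests, each refitting the model 100 times,
remain cheap.

What the generator does *not* emulate: volume-conducted artifact
topographies (blinks, EMG), latency jitter, impedance drift across blocks,
or realistic electrode geometry. Passing the recovery and comparison tests
therefore shows the estimator chain is correct under the stated model, not
that real recordings meet its assumptions.

## Evaluation metrics

- **PSD / SNR.** Per-trial periodograms (one-sided, scaled so the non-DC
  bins of a trial sum to its population variance) averaged over trials;
  SNR is the power fraction in the bin nearest the stimulation frequency
  over all non-DC bins up to Nyquist, hence in [0, 1]. The denominator
  range is parameter-free; bandpass filtering already bounds the content.
- **Map and component correlations.** Plain Pearson correlations; the
  spatial-reproducibility summary is the mean ± SD over unordered map
  pairs.
- **Cluster separation.** Single-trial components (z-scored per trial so
  structure reflects waveform shape, not per-subject amplitude) are
  embedded in 2-D with scikit-learn's t-SNE (perplexity 30, fixed seed) and
  scored with Fisher's discriminant ratio, implemented as
  trace(between-class scatter)/trace(within-class scatter); a vanishing
  within-class scatter with separated classes returns +inf rather than
  crashing. t-SNE is stochastic, so only order relations between FDR
  values of different pipelines (group vs per-subject vs single channel)
  are treated as meaningful.
- **Best-channel baseline.** The channel whose trial-averaged spectrum
  concentrates the most power at the stimulation frequencies, summed over
  conditions — the synthetic analogue of picking Oz for SSVEPs.

## Known limitations

- The method applies to epoched data only; there is no path for analyzing
  continuous data without trial onsets.
- No artifact rejection or montage handling beyond channel labels.
- The predictive filter assumes the candidate-condition models share the
  new trial's channel count and trial length.
- Scalp-map recovery correlations are computed in normalized channel
  space, which compresses large mixing weights when per-channel noise is
  inhomogeneous; at low snr the worst-case map correlation degrades before
  the component correlations do.
- The resampling test requires inter-trial slack (see above) and is mildly
  conservative under strongly autocorrelated background activity.
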