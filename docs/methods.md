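# Methods

This note documents the models, numerical choices and known limitations
of `astrorf`. It is the package's own account of its science; every
number quoted here is computed by the test suite or the acceptance
script, not asserted from elsewhere.

## Stimulus representation

The playback waveform (single channel, 250 kHz in the intended regime)
is converted to a power-spectral-density spectrogram by Welch-style STFT
segments of `nfft = 4096` samples with 50% overlap and a Hann taper. At
250 kHz this yields a hop of 2048 samples, i.e. a temporal resolution of
8.1920 ms, and a frequency grid of 61.035 Hz. The taper and the PSD
scale are conventional choices — both are exposed (`window`,
`log_power`) because neither is forced by the analysis design; the
default is raw PSD.

The frequency axis is restricted to the 45–110 kHz USV band and averaged
into 28 linear bins. Averaging (not summing) the constituent FFT bins
keeps units comparable when band edges leave unequal bin counts.

At each time bin `t ≥ 27` the stimulus history is the 28×28 patch of
bins `[t-27, t]`, flattened row-major (lag-major) to a 784-vector. The
first 27 bins yield no patch: dropping them fabricates no stimulus
history, and with a long leading silence in the stimulus design the
choice is immaterial. PCA is fit on the analyzed stimulus's own patches
(a single-stimulus design); the top-K eigenvectors (K = 128 by default)
with the patch mean define an affine projection, and the retained
variance fraction is recorded. Component signs are fixed by making each
component's largest-magnitude element positive, so bases are
reproducible across runs.

## Event responses

A per-trial fluorescence trace is segmented into excursions (contiguous
runs above a baseline, default 0 for synthetic traces, a configurable
quantile for real ones); within each excursion the event onset is the
first bin at which the signal reaches 10% of the excursion peak. Onsets
become a binary trials × bins raster, and the regression target is the
trial-averaged raster restricted to bins that have a patch.

Train/test and cross-validation splits are **contiguous temporal
blocks** (70/30, then 3 folds over the training block, remainder bins
assigned to the earliest folds). Overlapping 28-bin patch windows share
stimulus content between neighboring rows, so random row-level splits
would leak the test stimulus into training; block splits bound that
leakage to the single boundary. Seeded block-order shuffling is
available but off by default.

## The MNE encoding model

The second-order Maximum Noise Entropy model assigns

    P(event | s) = 1 / (1 + exp(a + s·h + sᵀJs))

with symmetric J, parameterized by its upper triangle. The fitted
objective is the average cross-entropy between the trial-averaged
response y ∈ [0,1] and the model probability — identical to the pooled
per-trial Bernoulli likelihood — plus a small ridge penalty
(default 1e-4) on h and J for stability when rows are scarcer than
parameters. At a stationary point with binary targets the gradient
components are exactly the moment mismatches, so the fitted model
matches the empirical mean rate, event-triggered average and
event-triggered covariance; the test suite verifies that these
mismatches shrink monotonically as the optimizer tolerance tightens.

Optimization is full-batch L-BFGS on the exact analytic gradient
(checked against central finite differences at 1e-6 relative). Two
numerical choices matter:

- **Internal standardization.** Raw PSD-scale PCA coordinates span many
  orders of magnitude, which stalls quasi-Newton methods at their
  gradient tolerance. The optimizer therefore works in per-dimension
  z-scored coordinates (statistics from the training rows) and the
  result is mapped back exactly — a pure reparameterization with no
  effect on predictions; reported (a, h, J) are in the original reduced
  coordinates. Predictions are invariant under any consistent invertible
  linear reparameterization (property-tested with random rotations).
- **Convergence, not early stopping, by default.** Each fold model is
  run to convergence under the ridge penalty; the held-out fold's NLL is
  recorded as that fold's score and the final parameters are the average
  of the three fold models (a deterministic ensemble). An early-stopping
  mode (`fit(early_stopping=True)`, parameters at the best validation
  NLL along the optimization path) is available, but it is *not* used by
  default because it breaks the feature-significance comparison below:
  shuffled-null fits stop almost immediately on their flat validation
  curves while real fits run long, leaving the null eigenvalue spectra
  systematically narrower than the real fits' noise spectra. Converged
  fits keep real and null models at comparable capacity.

## Significance

**Model significance** follows the shuffle-null design: the training
responses are permuted over training rows (the test pairing untouched),
the model is refit with identical settings, and the unshuffled test
stimuli are predicted; 200 such refits (configurable) form the null for
the observed test cosine similarity. The p-value is reported both as the
literal proportion of null values ≥ observed and under the (r+1)/(n+1)
permutation convention; the significance flag uses the literal
proportion at α = 0.05. The type-I error of this test on
stimulus-independent units is verified to sit inside the exact binomial
95% interval around 0.05 (100 units, 50 shuffles each).

**Feature significance** has no canonical definition for this model; the
package's convention is an extreme-eigenvalue (familywise) null: a
quadratic candidate is significant if its eigenvalue exceeds the 97.5th
percentile of the shuffled fits' *largest* eigenvalues or falls below
the 2.5th percentile of their *smallest*; the linear kernel is
significant if ‖h‖ exceeds the upper band edge of the null ‖h‖
distribution. Testing the extremes controls the error rate across all K
candidates jointly, so a stimulus-independent unit yields ≈ 0
significant features in expectation (a per-rank band does not: measured
against per-rank nulls, essentially all K bulk eigenvalues of a real fit
are flagged, because the bulk spectra of signal-bearing and shuffled
fits differ systematically in shape). The convention is recorded in
output metadata. Eigenvalue sign gives the class: λ > 0 increases the
exponent and therefore *decreases* event probability (inhibitory);
λ < 0 is excitatory. Eigenvector signs are fixed by making the
largest-magnitude element positive.

## Feature comparison and subspaces

The modulation power spectrum of a 28×28 feature map is the squared
magnitude of its unpadded 2-D DFT, zero-frequency centered, with axes in
cycles/s and cycles/kHz (Parseval: total modulation power equals
784 × the map's squared norm). It is invariant to circular temporal
shifts of the feature, which is what makes it a useful similarity
representation. Optional zero-padding refines the modulation sampling.
Spectra are embedded with UMAP and event-property vectors (duration,
area, rise time, fall time, circularity; z-scored — the scaling is a
package choice) are embedded and density-clustered with HDBSCAN; both
stages are seeded library plumbing, with the neighbor parameter
auto-reduced when points are scarce. A caution verified in the tests:
the nonlinear embedding can fabricate apparent density structure on
unstructured (single-Gaussian) data, so cluster counts on embedded data
should not be over-read.

Principal angles between pooled significant-feature sets use
rank-revealing (pivoted) QR for the orthonormal bases, dropping columns
numerically dependent at relative tolerance 1e-10, and arccos of the
singular values of Q_aᵀQ_b, clipped to [0,1]. This is provably
equivalent to the recursive nested-maximization definition; the test
suite keeps an independent alternating-maximization oracle and a
`scipy.linalg.subspace_angles` cross-check, both agreeing to well under
1e-3 degrees. "Full stimulus space" means the retained K-dimensional
PCA subspace, where the features live by construction; the 784-dim
ambient alternative is available. Features are pooled per population
before QR, giving one angle curve per population pair.

## Synthetic data

The generator emulates the study conditions, not the biology:

- **Stimulus**: `n_segments` segments of 8 s, each padded by 1 s of
  exact-zero silence on both sides, after a 20 s lead silence; defaults
  give the 150 s + 20 s layout at 250 kHz. Each segment holds 2–6 FM
  sweeps per second (linear or sinusoidal FM, duration 30–150 ms,
  extent ≤ 30 kHz, confined to 45–110 kHz, Hann envelopes, fixed
  segment RMS). ≥ 99% of segment power lands in band (verified). No
  claim of bioacoustic fidelity is made — sweep statistics only
  qualitatively mimic USV syllables.
- **Ground truth**: feature templates are Gabor-like localized
  time–frequency blobs (the qualitative shape of recovered receptive
  fields, and easy to verify recovery against). Templates are projected
  into the reduced space, re-orthonormalized by QR (Gram–Schmidt), and
  assembled into J = Σ λᵢvᵢvᵢᵀ; probabilities are logistic and hence
  always in (0,1).
- **Rasters**: independent Bernoulli draws per trial and bin at the
  model probability (trial averages converge to it; verified at 10⁴
  trials against binomial bands). The default base rate is 0.15 per
  8.192 ms bin with suppressive features keeping overall rates ≤ 0.3 —
  plausible sparse-event placeholders, exposed in config, since real
  per-bin CFU rates are not characterized.
- **Populations**: two unit groups whose true feature subspaces share
  exactly `shared_dim` directions, built by joint orthonormalization so
  the true principal angles are exactly 0°/90°.

What passing tests on these data do **not** show: robustness to the
temporal autocorrelation of real calcium indicators, to AQuA/CFU
segmentation errors, to non-Poisson event statistics, or to the strong
sparseness and collinearity of real vocalization spectrograms. On that
last point: patch coordinates of real (and realistic synthetic) audio
have variances spanning orders of magnitude, which makes eigenvector
recovery much harder at fixed data size than on well-conditioned
ensembles; the estimator-property tests therefore use unit-variance
Gaussian stimulus ensembles through the same simulation and fitting
machinery, while the audio path is exercised end-to-end in the pipeline
tests at realistic (harder) conditions.

## Problem sizes used in the tests

The test suite runs the estimator-property checks at sizes chosen to
make the statistics decisive on one CPU in a few minutes: parameter
recovery at N = 50,000 bins × 20 trials (K = 24), null calibration at
100 units × 50 shuffles (N = 400, K = 6), subspace recovery at
N = 8,000 (K = 24, 6 units, 25 shuffles), and the end-to-end audio
pipeline at 1–2 stimulus segments with reduced K. The full-scale
defaults (150 s stimulus, K = 128, 200 shuffles) remain the package
defaults and run unchanged through the same code paths.

## Known limitations

- The shuffle null permutes training rows independently, which destroys
  the (weak) temporal autocorrelation of the trial-averaged response
  along with the stimulus pairing; for strongly autocorrelated real
  traces a block-permutation null would be more conservative.
- Fold-averaging of converged fits is a deterministic ensemble, not a
  refit at a CV-selected hyperparameter; the ridge strength is fixed,
  not tuned per unit.
- `evaluate()` retains the shuffled fits' parameters for the feature
  null, which is memory-proportional to `n_shuffles × K²`.
- The CLI's per-stage subcommands cover synthesis, stimulus processing
  and subspace comparison; model fitting is orchestrated through
  `astro-rf run` (or the library API) because it needs the full aligned
  context.
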