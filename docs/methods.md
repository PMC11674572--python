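# Methods

`connectodyn` implements a complete analysis chain for rapid
electrophysiological connectome-state dynamics and their relation to
cognition, together with a synthetic-cohort generator that makes every stage
verifiable by parameter recovery. This note documents the models, the
defaults and why they were chosen, the numerical choices, and what the
synthetic validation does and does not establish about real data.

## Signal preparation

Region-level source signals are band-limited within the canonical grid
(delta 1–3, theta 4–7, alpha 8–12, beta 13–25, gamma 30–45 Hz) using a
zero-phase FIR filter (Hamming window, forward–backward application). The
filter order follows the band: the transition width is `max(1, 0.25·lo)` Hz,
giving roughly 3.3·fs/width taps. Phase linearity was preferred over sharper
IIR roll-off because envelope timing feeds directly into the state model.

Regions whose time courses are numerically dependent on the others are
removed by column-pivoted QR on the time × region matrix: a region is
dropped when its pivoted R-diagonal falls below `tol` (default 1e-8,
relative) times the largest diagonal. Pruning is intended to run on
concatenated cohort data so that one region set serves all subjects; the
count of excluded regions is a property of the data, not a constant.

Source leakage (shared zero-lag signal) is removed by finding the closest
matrix of the form *orthonormal basis × per-region positive scaling* to the
input, alternating a polar decomposition with closed-form scale updates
(initialized at the polar factor of the input; convergence when the relative
Frobenius change is below 1e-10, at most 500 iterations; ties in degenerate
singular values resolve by input column order). The output has exactly
orthogonal rows and is closer to the input, in Frobenius norm, than
sequential Gram–Schmidt of the same columns (checked in the tests).

Amplitude envelopes are the magnitude of the Hilbert analytic signal,
anti-alias filtered and resampled to 40 Hz (polyphase resampling). The first
and last 0.5 s are trimmed in the full chain to discard Hilbert edge
transients.

## State model

Connectome states are the states of a K-state hidden Markov model with
multivariate Gaussian observations: each state k has its own mean and
covariance over regions, and the state sequence follows a homogeneous Markov
chain. K defaults to 6; the intent is a useful granularity of description,
not a "true" number of states, so K is configuration, never estimated.

Fitting is maximum-likelihood EM on the concatenation of subjects, each
subject an independent sequence restarted from the initial distribution, with
per-subject standardization (each region demeaned and scaled to unit variance
within subject) to remove subject-level amplitude offsets before pooling.
Design choices:

- **Restarts and initialization.** `n_restarts` (default 5; 2–3 suffice for
  well-separated synthetic states) k-means initializations on a ≤50k-sample
  subsample, per-restart seeds derived from the master seed; the best run by
  final log-likelihood wins, ties broken by restart index.
- **Regularization.** Each M-step adds `1e-6 · trace(S)/R` to the covariance
  diagonal; if a covariance is still not positive-definite the fit aborts,
  naming the state.
- **Convergence.** Relative log-likelihood change below 1e-6, at most
  `max_iter` (default 100) iterations. The log-likelihood trace is stored and
  asserted non-decreasing in the tests.
- **Inference flavor.** EM point estimates rather than variational Bayes:
  the downstream phenotypes need only expected state statistics, and the
  validation criterion is recovery of known synthetic parameters.

The forward/backward/Viterbi recursions are scaled probability-domain
loops compiled with numba; they are verified to 1e-8 against exhaustive
enumeration over all K^T paths on small instances, and the forward
log-likelihood additionally against an independent HMM library.

The temporal-null surrogate draws states i.i.d. from a fractional-occupancy
profile and emits from the fitted state Gaussians: the time-collapsed
covariance equals the analytic mixture covariance
Σ_k fo_k (C_k + μ_k μ_kᵀ) − m mᵀ while all sequential structure is destroyed
(lag-1 state autocorrelation ≈ 0 versus > 0.5 for a sticky chain).

## Phenotypes

Fractional Occupancy is the time-average of the posterior state
probabilities (a K-simplex). Transition Probability is the row-normalized
matrix of expected transition counts from the forward–backward pass
(default); a Viterbi hard-count variant is available behind a flag for
sensitivity checks. Soft counts use the full posterior and have lower
variance at short recordings. Rows of unvisited states are set uniform and
flagged, so downstream standardization can drop or impute them.

Band feature vectors are assembled by role: `tp_only` takes the K(K−1)
row-major off-diagonals (30 at K = 6), `fo_only` the K occupancies, and
`composite` their concatenation (36 at K = 6). Feature order is fixed and
named (`TP1-2`, …, `FO1`, …) because PCA results depend on a consistent
column order. The default band→role map is the heritable-phenotype set:
theta and alpha contribute TP, beta FO, gamma the composite.

## Association analysis

All variables are z-scored. Subjects missing more than 50% of the cognitive
measures are excluded; remaining missing entries are mean-imputed after
standardization. Per band, PCA on the feature correlation matrix retains
components with eigenvalue > 1 (Kaiser); retained PCs from all bands are
concatenated into U in the configured band order. The cognitive side is
reduced by maximum-likelihood factor analysis (Lawley profile likelihood
over uniquenesses, bounded below at 0.005 to guard Heywood cases) with the
factor count set by the Kaiser rule, followed by promax rotation
(varimax, then least-squares fit to the |loading|^κ target; κ = 4, the
conventional default). Factor scores are computed by both the regression
(Thurstone; optional ridge on the correlation matrix) and Bartlett methods;
regression scores enter the CCA, and the two are checked to agree (r > 0.95)
on planted structure.

Age and sex are regressed out of both U and V (OLS with intercept) before
CCA and before permutation — the residualize-then-permute scheme is the
simplest one consistent with covariate-adjusted inference.

CCA is solved by SVD of the product of the two orthonormal column bases;
rank deficiency is handled by solving on the reduced-rank subspace with a
warning. Parametric per-mode p-values use Bartlett's chi-square
approximation of Wilks' lambda. Permutation inference permutes whole rows of
U against a fixed V (a subject's feature vector moves as a unit);
optionally, family blocks move as units among blocks of equal size, because
twin pairs are not exchangeable with singletons — both schemes are provided
since either reading is defensible. Each permutation contributes its first
canonical correlation to the null, and every mode is compared against that
max-statistic null (familywise control); p = (1 + #{null ≥ r_k})/(n_perm+1).
Canonical loadings are plain Pearson correlations of each original variable
with its side's mode score, with two-sided t-based p-values and no
multiple-testing correction (per-variable stars, flagged as such).

The variance contribution of PC j to a feature subset is
Σ_{i∈subset} coeff_ij² λ_j / |subset| × 100 — the squared structure loading
per standardized variable averaged over the subset. This definition is
self-consistent (contributions over all PCs sum to 100%) and matches
per-variable regression R² on PC scores, but other definitions exist; it is
documented here precisely because it is a choice.

## Synthetic cohorts

The generator emulates, with known ground truth: Markov state paths,
state-conditional Gaussian envelopes at 40 Hz, optional amplitude-modulated
raw carriers for exercising the signal-prep chain, twin-pair structure
(pairs share family id, sex, age, and correlated latent dynamics), age/sex
confounds on both sides, and a 15-measure battery with a 5-factor simple
structure. Defaults mirror the targeted study conditions: 926 subjects, all
paired, K = 6, four heritable bands, 6 minutes of envelope at 40 Hz, and a
planted canonical mode of 0.25. Validation runs use smaller cohorts
(e.g., 20 subjects × T = 2000 for state recovery; 600 subjects for mode
recovery), chosen as the smallest sizes at which the sampling error of the
recovered quantities is well inside the assertion tolerances.

Two design points deserve emphasis:

- **Low-rank subject variability.** Per-subject transition matrices are
  log-domain perturbations of the base chain along a small set (default 2)
  of fixed direction matrices, one of which is sparse (entries in distinct
  rows) and defines the planted TP feature set. Between-subject TP variance
  therefore has a low-rank structure that Kaiser-retained PCs capture — as
  systematic individual differences in real data plausibly do. With
  full-rank i.i.d. entry noise instead, Kaiser retention on near-uncorrelated
  features would be arbitrary and truncation of the planted direction would
  reflect the toy noise model rather than the pipeline.
- **Calibrated planted mode.** Cognition's first latent factor carries
  α·s, where s is the standardized planted combination of realized
  (residualized) TP features and α = r/ρ, with ρ the analytic multiple
  correlation of the factor with the measures given the loadings and noise.
  The population first canonical correlation between features and measures
  then equals the requested `planted_mode_r` exactly; an unreachable request
  (r ≥ ρ) raises an error rather than silently under-planting.

Emissions are exact Gaussians (optional rectification off by default)
because the validation target is recovery within the model class. What
passing tests therefore show: the estimator machinery is correct and the
pipeline recovers planted effects of realistic size at realistic n. What
they do not show: robustness to non-Gaussian envelopes, model-order
mismatch, volume conduction beyond linear zero-lag leakage, or the true
generative covariance of any particular cognitive battery.

## Degenerate inputs and edge behavior

Non-stochastic transition matrices, off-simplex distributions, non-PD
covariances, non-finite observations, bands beyond Nyquist, rank-deficient
covariates, empty feature subsets, and unknown band roles all raise
validation errors. All-zero inputs to collinearity pruning return an empty
set with a warning. K = 1 reduces to closed forms (pooled mean, unit
posteriors). Permutation p-values are bounded below by 1/(n_perm+1) by the
add-one estimator.

## Known limitations

- No sensor-space preprocessing, artifact handling, or source localization:
  the pipeline starts at region × time signals.
- One HMM per band with a shared group-level model and per-subject decoding;
  subject-specific (dual-estimated) observation models are not implemented.
- The parametric CCA p-value is an asymptotic approximation; the permutation
  p is the primary inference.
- Figures are not generated; results are tables and JSON.
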