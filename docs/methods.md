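# Methods

## The model

`hyperclass` treats the actor's and the observer's multivoxel BOLD activity
as two views of one latent process.  With per-voxel standardized data
(training-run statistics), the generative model is

    x_m(t) = W_m z(t) + ε_m(t),          m ∈ {actor, observer}
    z(t) ~ N(0, I_K)
    W_m[:, k] ~ N(0, α_mk⁻¹ I_Dm)        (group-wise ARD, per view × component)
    α_mk ~ Gamma(a₀, b₀),  τ_m ~ Gamma(a₀, b₀),  ε_m ~ N(0, τ_m⁻¹ I)

Inference is mean-field variational Bayes with the standard closed-form
coordinate updates for q(Z), q(W_m), q(α), q(τ), monitored by the evidence
lower bound.  Hyperpriors are effectively flat (a₀ = b₀ = 1e-12); the
latent dimensionality K is an upper bound and the ARD prior prunes excess
components per view.

**Component typing.**  A component's relevance in a view is its expected
squared loading norm E[‖w_mk‖²] (posterior mean plus the ARD-shrunk
covariance term).  A component is *present* in a view when its relevance
exceeds 1e-3 × the view's maximum **and** explains at least 0.2% of
per-voxel standardized variance.  Present in both views → shared; in one →
view-specific; in neither → inactive.  Two numerical facts drove this
rule.  First, mean-field ARD drives a pruned component's precision up
roughly linearly per sweep, so its *linear* loading-norm ratio decays only
as 1/√sweeps; the squared (variance) scale separates pruned from active
components by 1–2 orders of magnitude at ELBO convergence, where the
linear scale would need ~1e5 sweeps.  Second, the relative rule alone
degenerates on null data (when every component is noise-level, all ratios
are large), so the absolute floor — set a factor of several above the
Marchenko–Pastur noise-eigenvalue level for the canonical 288-sample,
500-voxel fold, and an order of magnitude below the benchmark's weakest
genuine shared component — is what makes "two independent-noise views → 0
shared components" hold across seeds.

**Realignment.**  Given new observer activity x_o, the latent posterior
mean under the plug-in loadings is E[z|x_o] = S τ_o W_oᵀ x_o with
S = (I + τ_o W_oᵀ W_o)⁻¹; the predicted actor activity keeps only the
shared coordinates, x̂_a = W_a[:, shared] E[z|x_o]_shared.  View-specific
components still participate in the posterior — they explain away
observer-specific variance before the shared part is read out.  The
transform is the plug-in posterior mean (not the full posterior
predictive); realigned output is returned in standardized actor units, and
the downstream decoder is trained on identically standardized actor data
so the two spaces match.  With zero shared components the prediction is
identically zero (and decoding sits at chance), with a warning.

**Determinism.**  Initialization is a randomized SVD of the concatenated
views plus small seeded jitter; the fit is a pure function of
(data, K, seed).  Defaults: tol = 1e-6 relative ELBO change,
max_iter = 1000 (typical fits converge in 100–300 sweeps).

## Decoding

Four one-vs-rest binary logistic models, one per action, each with a
univariate Laplace prior of common scale b on every voxel weight.  The
posterior is summarized by its mode — an L1-penalized logistic fit
(liblinear, C = b) — plus per-weight scales from a diagonal Laplace
approximation of the curvature at the mode.  This keeps the decoding
contract (calibrated probabilities in (0,1), argmax class assignment,
sparsity monotone in b) while remaining cheap enough for nested
cross-validation; a notice is logged at first use.  Features are
standardized with training-fold statistics.  The four binary probabilities
are not renormalized before the argmax (argmax is invariant to it); exact
ties go to the lowest class index.

## Cross-validation and hyperparameters

Leave-one-run-out throughout: 4 training runs (288 samples) vs 1 test run
(72 samples); each binary training fold holds 72 target vs 216 non-target
samples.  In hyperclassification the BCCA model is fitted per fold on the
four paired runs only — the held-out run and all labels are invisible to
it.  Hyperparameters (K ∈ {20,…,100}, b ∈ {0.01,…,100}) are selected
leave-pair-out: each pair adopts the grid point maximizing mean accuracy
over the *other* pairs, with a fixed evaluation seed for comparability;
a single pair falls back to the grid midpoint with a warning.  Empirical
chance permutes training-side labels within run (preserving per-fold class
balance).  Mean accuracies carry Student-t confidence intervals; fold-mean
accuracy is primary, sample-pooled accuracy is also reported.

## Diagnostics

*ISC.*  One Pearson r per voxel per pair over all 360 samples
(zero-variance voxels get r = 0, flagged).  Pre- vs post-realignment maps
are Fisher-transformed and compared with a two-sample t-test treating the
two groups as independent — deliberately matching the analysis convention
this package reproduces, although a paired test would be more powerful; a
`paired=True` flag provides the latter.  Benjamini–Hochberg FDR at
q = 0.05 precedes a cosmetic 125-voxel cluster-extent filter
(6-connectivity), in that order.

*Searchlight kNN.*  A 6-mm-radius searchlight on a 4-mm grid holds 19
voxels (radius, not diameter: the only reading consistent with 19 voxels);
per pair, each of the 120 trials is summarized by its flattened 3-scan ×
19-voxel pattern (57 points) and the 120×120 actor × observer trial
correlation matrix is classified by majority vote among the k most
correlated actor trials, averaged over k = 1, 7, …, 115 to damp small-k
noise.  Observer trials are classified against actor trials as the
reference set (matching the hyperclassification direction); vote ties go
to the class of the most correlated trial among the tied classes.  The
pre/post accuracy contrast uses a sign-flip permutation t-test across
pairs (1000 flips default) with BH-FDR, displaying increases above 5
percentage points.

*Falsification probes.*  (1) Temporal shuffling permutes the observer's
sample rows while labels keep their original positions (scan-level by
default, trial-level and circular-shift modes available).  (2) Surrogates
are per-voxel phase randomizations preserving the amplitude spectrum
exactly (independent voxels; no cross-voxel phase coupling).  (3) Control
ROIs re-run the full pipeline on caller-supplied masks.  All three must
land inside the 95% binomial band around 25%.

## The synthetic generator

The generator emulates the study design: 5 runs × 24 trials (6 per class),
3 retained scans per trial at TR = 2 s, a 6-s lag handled by a
double-gamma haemodynamic kernel whose positive lobe peaks at the lag, 500
voxels per view on a compact 4-mm grid with a contiguous 160-voxel signal
block, 4 shared class latents plus 3 view-specific latents per view
(AR(1), amplitude matched to the signal), and AR(1) Gaussian noise
(coefficient 0.3, unit sd).  Under `misalignment="rotation"` the
observer's shared loadings are a random orthogonal mix of the actor's over
the signal voxels — informationally identical, spatially incompatible.
Trials are spaced 10 scans apart (a desk-scale compression of the ~28-s
trial cycle; the HRF has largely decayed between onsets).

`effect_size` (class-latent amplitude at HRF peak, in noise-sd units)
defaults to 0.1.  This value was chosen once, by scanning for the regime
that reproduces the method's qualitative signature at realistic levels —
within-subject decoding around 65–75%, raw between-subject decoding at
chance, hyperclassification in between — rather than the ceiling-saturated
100% that stronger signals give.  What the generator does *not* emulate:
spatially correlated noise, subject motion, physiological confounds,
scanner drift, nonlinear haemodynamics, or imperfect trial pairing between
actor and observer sessions.  Passing tests therefore demonstrate the
pipeline's statistical machinery and its falsifiability logic, not
performance on real scans.

## Problem sizes used in tests

The test suite exercises the full design (5 runs, 360 samples, 500 voxels)
for the benchmark triplet and the chance probes at 5 seeds each; BCCA
recovery uses 500 samples × 60 voxels per view; the ISC contrast uses 10
pairs at 343 voxels with a planted 150-voxel region; searchlight
calibration uses analytic 120×120 matrices.  These sizes were chosen so
the whole suite completes in about a minute while every assertion runs at
the canonical per-fold sample counts.

## Known limitations

- Mean-field VB underestimates posterior variance and, without
  parameter-expanded rotations, can retain weak noise components at the
  Marchenko–Pastur eigenvalue level; the absolute relevance floor handles
  their classification but their loadings are not driven numerically to
  zero.
- The decoder's posterior summary is a mode + curvature approximation, not
  a full expectation-propagation posterior; predictive probabilities are
  plug-in, not posterior-averaged.
- The two-sample (rather than paired) ISC group test follows the
  reproduced convention and sacrifices power.
- Realignment is strictly linear and time-instantaneous; lagged or
  nonlinear coupling between brains is out of scope, as are more than two
  views.
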