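# Methods

This note documents the models, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## Generative model (`synth`)

Each subject's ROI signal is the sum of three sources:

    x_{s,r}(t) = λ_{s,r} · S_r(t) + I_{s,r}(t) + N_{s,r}(t)

- **S** — stimulus-evoked signal, drawn once per cohort: a Gaussian process
  with spatial covariance `stimulus_cov` (unit diagonal) and AR(1) temporal
  smoothing (`ar1_coef`, default 0.6 at TR = 2 s, chosen so the band-pass
  filter acts on a realistically red spectrum). Every subject receives the
  same realization, scaled per ROI by loadings λ ~ N(`loading_mean`,
  `loading_sd`²). Subject-to-subject loading variation is the mechanism by
  which ISFC features can carry individual-difference signal.
- **I** — intrinsic signal, drawn independently per subject with covariance
  `intrinsic_base_cov + fingerprint_sd · Δ_s`, re-projected to PSD by
  eigenvalue clipping. The perturbation Δ_s mixes two parts controlled by
  `fingerprint_structure ∈ [0, 1]` (default 0.5): a *shared axis* — a uniform
  off-diagonal pattern scaled by a per-subject scalar u_s, emulating the
  dominant integration–segregation dimension along which intrinsic
  connectomes empirically vary — and idiosyncratic symmetric edge noise.
  The shared axis matters: purely idiosyncratic perturbations make FC
  features pairwise uncorrelated across subjects, and then no linear model
  can recover removed features from retained ones, which is unlike real
  connectivity data and would make dimensionality controls meaningless.
- **N** — white Gaussian noise of scale `noise_sd`.

Motion is a slow random walk (0.02 mm / 4e-4 rad steps) with spike steps of
3 mm at rate `spike_rate` per TR. Spikes enter the motion parameters only;
the BOLD-like signal itself is left clean so that degenerate analytic limits
(below) remain exact.

Behavioral scores: `raw = Σ_f w_f z_f + covariate effects +
N(0, score_noise_sd²)`, where `z_f` are the cohort-standardized connectivity
features named in `effect_spec`, then an affine clamp
`score = clip(0.5 + (raw − mean)/(8·SD), 0, 1)` maps raw scores into [0, 1]
like a proportion-correct test score. The clamp is monotone, so rank-based
evaluation is unaffected, and its offset/scale are recorded in
`ground_truth` so the declared weights remain identifiable (the test suite
recovers them to < 5% at n = 500 with zero score noise). Covariate columns
(age, age², gender, handedness) are standardized before weighting.

Defaults mirror the study's scale (90 children, 32 adults, 32 ROIs, 168 TRs
at TR = 2 s); tests and the acceptance script scale down explicitly.

What the generator does *not* emulate: hemodynamics, physiological noise
beyond white noise and spikes, voxel-level structure, spatially varying
smoothness, and any true developmental link between age and neural
maturation (ages are drawn independently of the neural parameters). Passing
tests therefore validate the *statistical machinery* — estimator identities,
calibration, and the logic of the joint-model comparison — not claims about
real developmental data.

## Preprocessing (`prep`)

Per-subject order of operations: artifact detection → temporal interpolation
→ nuisance-PC regression → simultaneous band-pass + detrend → drop the first
10 TRs → scrub marking → subject exclusion.

- **FD**: Power-style framewise displacement, `Σ|Δtrans| + 50 mm · Σ|Δrot|`,
  `fd[0] = 0`. The head radius is configurable.
- **Artifacts** (interpolated): FD > 2 mm or |global-signal z| > 3, z-scored
  against the subject's own mean/SD; flagged TRs are replaced by per-ROI
  linear interpolation between the nearest clean neighbors (nearest clean
  value at the boundaries — chosen for determinism).
- **Nuisance regression**: the first `n_pcs` principal components of a
  column-centered nuisance matrix are projected out (residuals centered).
  The cohort-level pipeline uses the six motion parameters as the nuisance
  source, clipped to their rank; explicit nuisance matrices (e.g., noise-ROI
  series) can be passed directly.
- **Band-pass + detrend**: one least-squares projection removing Legendre
  polynomials (orders 0–2) and sine/cosine pairs at every DFT frequency
  outside 0.008–0.15 Hz. Being an orthogonal projection it is idempotent,
  and it equals an explicit least-squares solve against the full regressor
  matrix. Note the inherent overlap at the low band edge: the detrending
  polynomials share energy with the lowest in-band bins, so sinusoids below
  ~0.025 Hz (at 100 TRs, TR = 2 s) are partially attenuated. This is a
  property of the joint projection itself, not an implementation artifact.
- **Scrubbing and exclusion**: TRs with FD > 1 mm are *masked*, not deleted,
  so child and adult TR grids stay aligned for ISFC; subjects with mean
  FD > 0.5 mm, or fewer than 10 usable TRs, are excluded with a recorded
  reason.

Optional NIfTI ROI extraction dilates each atlas ROI by the 6-neighborhood,
resolves overlaps by distance to the original ROI (ties to the lower label),
intersects with the group mask, and drops ROIs with < 5 surviving voxels.

## Connectivity (`connectivity`)

FC is the Pearson correlation over a subject's admissible TRs. The reference
signal is the per-TR mean over adults whose scrub masks admit that TR
(`reference_mode="per-adult"` instead averages child-vs-single-adult ISFC
matrices; both coincide in the noise-free limit, and the mean-reference is
the default). ISFC is the child-vs-reference cross-correlation matrix,
symmetrized as `(raw + rawᵀ)/2`; its diagonal (ISC) is unchanged by
symmetrization. Correlations are Fisher-transformed (artanh) with values
clipped to ±(1 − 1e−7) first, since artanh(±1) diverges.

Features are vectorized in row-major upper-triangle order and named
`FC:a-b`, `ISFC:a-b`, `ISC:a`; for R ROIs there are R(R−1)/2 FC features and
R(R+1)/2 ISFC features (edges + ISC). Standardization is per feature across
subjects, with statistics fitted on training rows only; features constant on
the training rows are zeroed with a warning.

FC–ISFC similarity is the Spearman correlation between a subject's
Fisher-transformed ISFC and FC edge vectors, ISC diagonal excluded. Its
correlation with age and score uses an exact permutation p-value for n ≤ 8
and the asymptotic one otherwise.

## PLS1 (`pls`)

NIPALS with deflation of X only (y-deflation is redundant for a univariate
response). Per component: `w ∝ X_dᵀy` (unit norm), `t = X_d w`, loadings
`p = X_dᵀt/tᵀt`, `q = yᵀt/tᵀt`, then `X_d ← X_d − t pᵀ`. The regression
vector on the original centered predictors is `β = W(PᵀW)⁻¹Q`, which maps
the weights through the deflated spaces so that `ŷ = X_c β + ȳ` equals the
sequential fit. Centering only — variance scaling is the caller's
responsibility, keeping a single normalization site in the feature pipeline.
The fit is deterministic; models serialize to JSON. Degenerate situations
(constant y, vanishing covariance at some component, k outside
[1, min(n−1, p)]) raise informative errors rather than returning silently
ill-defined components.

## Prediction experiment (`predict`)

- Fold partitions depend only on `(seed, repeat)` and are shared across
  feature sets and component counts: every comparison (FC vs ISFC vs joint,
  full vs reduced) is paired on identical partitions.
- Covariate control residualizes the *response* on [1, age, age², gender,
  handedness], fitted per training fold and applied to the held-out fold;
  models are scored on that residual scale. Residualizing y (not X) matches
  the goal of predicting score variation not explained by demographics and
  avoids test-fold leakage.
- Per repeat, held-out predictions are pooled across the folds and scored by
  MAE and Spearman rho; summaries average over repeats. Component selection
  minimizes mean MAE, ties toward fewer components. Selection and reporting
  share the same CV (as in the analysis this reproduces); a nested scheme
  would be less optimistic but is out of scope here.
- Permutation test: y rows (with their covariate rows) are shuffled against
  the features; the identical pipeline is rerun at the selected k on the
  same partitions; one-sided `p = (1 + #{null ≥ observed}) / (1 + B)`.
- Half-edge control: each repetition draws half of the FC and half of the
  ISFC features without replacement, reruns the CV, and is paired with the
  single-measure models on the same partition; one-sided paired t-tests ask
  whether the reduced joint model still wins.
- Spearman partial correlation ranks all variables (x, y, and each control),
  residualizes the ranked x and y on the ranked controls, and correlates the
  residuals; with a single control this reproduces the classic closed form
  exactly.

## Importance (`importance`)

Leave-one-region-out removes, per ROI, all FC edges and/or all ISFC features
incident to it (the ROI's ISC entry counts as an ISFC feature), reruns the
CV on matched partitions at the full model's selected k — holding k fixed
isolates feature removal from model-order effects — and tests Δrho with a
one-sided paired t-test over repeats (removal is hypothesized to lower
performance), Bonferroni-corrected over ROIs. Coefficient degrees average
β across models, reshape by block into symmetric matrices, and sum absolute
coefficients per ROI row.

## Problem sizes

Simulation-based checks run at deliberately small scale — cohorts of ~24–60
children, 6–12 ROIs, 100–168 TRs, repeat counts of 1–20, and hundreds rather
than tens of thousands of permutations — sizes at which every stage's
statistical behavior (calibration, recovery, ordering of models) is already
measurable. All defaults for the full-scale analysis (100 repeats, 50,000
permutations, 1,000 subsample draws) remain available through the
configuration objects.

## Known limitations

- The ISFC reference requires adults scanned on the same TR grid; TRs with
  no valid adult are dropped from every child's correlation.
- The permutation test reuses the observed partitions; with very few
  repeats the observed statistic is itself noisy (mitigated by pairing).
- The motion model has no signal-coupled component, so nuisance regression
  on motion PCs cannot be shown to *improve* feature quality here — only to
  behave correctly as a projection.
- The leave-one-region-out t-test treats CV repeats as exchangeable
  replicates; repeats share data, so its p-values are anti-conservative in
  absolute terms and are best read as a paired ranking device, as in the
  analysis this package reproduces.
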