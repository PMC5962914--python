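# Methods

This note documents the models implemented in `svdnet`, the assumptions and
numerical choices behind them, what the synthetic data generators do and do
not emulate, and the known limitations.

## Coordinate and tensor conventions

Volumes use a 0-based, half-open voxel index convention; the center of voxel
(i, j, k) lies at `affine @ (i+0.5, j+0.5, k+0.5, 1)` in world millimeters.
Diffusion tensors are symmetric 3×3 matrices in mm²/s. FA and MD are always
computed from the eigenvalues of the stored (or interpolated) tensor:
MD = λ̄, FA = √(3/2)·‖λ − λ̄‖/‖λ‖, with FA defined as 0 for the zero tensor
in vectorized code paths and an explicit error in the scalar API.

## Tensor phantoms

A phantom is a background of isotropic tensors (default diffusivity
0.8×10⁻³ mm²/s, FA exactly 0) plus fiber tubes: hard-edged cylinders (or
circular-arc tubes) whose voxels hold an axially symmetric tensor
`λ⊥ I + (λ∥ − λ⊥) t tᵀ` with `t` the local centerline tangent. Hard-edged
membership (no partial-volume blending) keeps analytic expectations exact:
every in-tube voxel has identical FA, so, for example, the MD histogram of a
healthy tube has NPH exactly 1. The default tube eigenvalues
(1.7, 0.2, 0.2)×10⁻³ mm²/s give FA ≈ 0.8704.

The final 5 mm of each tube is labelled with the tract's two endpoint region
ids, guaranteeing that streamline endpoints land in parcels; all other voxels
are background (label 0). Overlapping tubes whose tangents disagree by more
than 1° are an error unless an explicit `blend="average"` policy is chosen.

Lesions are spheres inside which the tensor becomes
`md_scale · (fa_scale · D + (1 − fa_scale) · MD · I)`: MD is multiplied by
exactly `md_scale` (≥ 1) and eigenvalue deviations from their mean shrink by
`fa_scale` ∈ (0, 1]. Voxels outside all lesions are bit-identical before and
after insertion.

Default grid: 64³ voxels at 2.5 mm isotropic (the acquisition resolution the
pipeline emulates); tests and the reproduction script use smaller grids
(e.g. 32×12×12) that fully contain their tubes, purely as a problem-size
choice.

## Tractography

Deterministic tensorline tracking with the protocol parameters as defaults:
seed grid 0.5 mm (5×5×5 sub-seeds per 2.5 mm voxel, eligibility tested at the
interpolated seed location, FA ≥ 0.2), step 0.5 mm, stop at FA < 0.2 or
per-step turn > 45°, streamlines kept between 20 and 250 mm.

Numerical choices, configurable but fixed as defaults:

- **Interpolation**: component-wise trilinear interpolation of the tensor,
  eigen-decomposed at each step (smoother than nearest-neighbour and the
  standard choice for tensorline methods). Outside the grid the interpolant
  decays to the zero tensor, which reads as FA 0 and terminates the branch.
- **Integration**: fixed-step Euler along the principal eigenvector.
- **Angle rule**: compared between successive step directions (a per-step
  turn), not cumulative.
- **Eigenvector sign**: each step takes the orientation maximizing the dot
  product with the previous direction; the seed's two branches start along
  the raw eigenvector and its negation and are concatenated through the seed.

There is no randomness anywhere in tracking: identical volumes and
parameters give bit-identical streamline sets.

On a discretized straight tube the tracked length equals the axial extent of
the in-tube voxel centers plus an interpolation margin at each end: the
blended tensor `(1−α)·D_tube + α·D_background` stays above FA 0.2 up to a
fraction α* of the inter-center gap solvable in closed form (α* ≈ 0.82 for
the default eigenvalues). Tests compare tracked lengths against this
analytic support, not against the nominal tube length, so agreement is
required to within one step per branch end.

## Connectome construction and network measures

Edge weight between regions A and B: half the sum of inverse streamline
lengths (1/mm) over streamlines with one terminal point in each region (the
factor ½ corrects for the seeds-per-millimeter seeding scheme). Endpoint
lookup is nearest-voxel without dilation (phantom end caps make endpoints
unambiguous; a dilation radius is available for robustness studies).
Self-connections and streamlines touching background are excluded and
counted. Edges with weight < 1 are removed as likely false positives; the
comparison uses a 10⁻⁹ additive tolerance so floating-point accumulation
cannot drop an edge sitting exactly on the threshold. No ROI-volume
normalization is applied.

Efficiency uses the standard weighted-connectome convention length = 1/weight.
Global efficiency is the mean over ordered node pairs of the inverse
weighted shortest-path length (1/∞ = 0 for disconnected pairs); shortest
paths come from Dijkstra on the dense length matrix, and the test suite
verifies agreement with an independent triple-loop Floyd–Warshall oracle to
10⁻¹⁰. Mean local efficiency is the mean over nodes of the global efficiency
of the node's neighbourhood subgraph (neighbours of i, excluding i); nodes
with fewer than two neighbours contribute 0. This particular weighted
local-efficiency variant is a documented choice — it is oracle-tested, not
claimed to match any external implementation bit-for-bit.

## MD-histogram normalized peak height

NPH = (count in modal bin) / (in-range count), ties broken toward the lower
bin. Bins are fixed in absolute MD units (default width 0.05×10⁻³ mm²/s over
0–4×10⁻³ mm²/s) rather than data-driven, so longitudinal comparisons share a
common grid and NPH change is never confounded with binning change. The
white-matter mask in the synthetic pipeline is the set of in-tube voxels,
giving the whole-white-matter measure an exact phantom analogue.

## Cohort simulation

One latent standard-normal deviate per subject drives the network
global-efficiency slope; every other measure's random slope is a correlated
mixture `ρ·z_eff + √(1−ρ²)·z_m`, and intercepts correlate with their own
slopes. Visit values are intercept + slope·t + Gaussian residual; visits are
the annual schedule (MRI 0–3 y, cognition 0–5 y) with ±0.15 y uniform jitter
and exponential dropout (default hazard 0.12/y). Lacune and microbleed
counts accrue as Poisson increments whose subject rate scales with
`exp(−0.5·z_eff)` (faster network decline, more new lesions) and are
reported as raw cumulative counts; downstream analysis dichotomizes change
(any new lesion) or uses log₁₀(count+1), the +1 offset handling zeros.

Dementia conversion: `logit P = γ₀ + γ₁·z(slope) + γ₂·z(baseline)` with
γ₁ = −1.8, γ₂ = −0.5 per SD and γ₀ solved (Gauss–Hermite + Brent) so the
marginal rate equals 17.5% regardless of the effect sizes. Conversion times
are truncated normal (3.3 ± 1.4 y within follow-up). The cognitive slope
model is the correlated-slope construction above (equivalent to
δ₀ + δ₁·slope_eff + noise with δ₀ = −0.027/y).

Default magnitudes anchor to the observed cohort: efficiency baseline
7.94 ± 2.30 and mean decline −0.1764/y with slope SD 0.09 (so subject slopes
span roughly −0.45 to 0.10); efficiency residual SD 0.1 so that 4-visit
slope estimates retain that spread; cognition slope SD 0.035 with
ρ = 0.55 so decline-tertile group means span roughly −0.0002 to −0.046;
lesion rates 0.28 (lacunes) and 0.65 (microbleeds) per person-year.

What the generator does **not** emulate: per-subject image time series at
cohort scale, task-level neuropsychology, non-linear trajectories,
informative (outcome-dependent) dropout, measurement floor/ceiling effects,
and scanner drift. Passing tests therefore demonstrate correctness of the
estimation machinery under a linear mixed-effects truth, not robustness to
real-data pathologies.

## Longitudinal models

The model per measure is `value_it = (β₀+u₀ᵢ) + (β₁+u₁ᵢ)·t + ε_it` with
unstructured (freely correlated) random-effect covariance. The default
engine is statsmodels MixedLM (REML, Powell optimizer — chosen because the
default optimizer flags spurious non-convergence on typical cohorts).
Significance of β₁ uses a t reference with df = n_subjects − 1, the
between-subject approximation appropriate for a random-slope time effect;
this is an approximation in the Satterthwaite spirit, not an exact
Satterthwaite computation, and its calibration is verified by simulation
(type-I error at nominal 5%). Per-subject quantities passed downstream are
the totals β₀+u₀ᵢ (baseline) and β₁+u₁ᵢ (annualized change) with the random
effects taken as conditional modes (BLUPs).

A two-stage fallback — per-subject OLS, DerSimonian–Laird pooling of slopes,
empirical-Bayes shrinkage toward the pooled mean — is provided both as an
explicit `method="two_stage"` and as the automatic path when the mixed model
fails; on balanced data the two engines agree closely and in the
zero-residual limit both return the generating slopes exactly. Subjects with
a single observation receive the population estimates, flagged
`shrunk_only`.

MRI rows acquired after dementia conversion can be censored
(`censor_post_dementia`); cognitive rows are always retained.

## Outcome models

Predictors (per-subject baselines and changes) are standardized to unit SD
by default, so logistic B is log-odds per SD (the study's scaling is not
stated; per-SD is this package's documented choice) and linear models also
report β = B·sd(x)/sd(y). Wald tests per predictor. Forward stepwise
selection starts from the intercept-only model, adds the candidate with the
largest AIC decrease, stops when no addition lowers AIC, and breaks exact
ties lexicographically by predictor name; the intercept-only model is a
legal final answer. VIFⱼ = 1/(1−R²ⱼ); exact collinearity is flagged as
infinite. Models are unadjusted by default; covariates can be added as extra
predictor columns.

The tertile illustration ranks subjects by annualized change, splits into
three near-equal groups (sizes differ by ≤ 1, the remainder joining the
high-decline side, so n = 97 gives 32/32/33), breaks ties by subject order,
and reports per-group conversion fractions and mean fitted cognitive slopes.

## Mediation

Mediator model M = α₀ + a·T, outcome model Y = β₀ + c′·T + b·M (logistic
link for binary Y). Continuous treatments use a 1 SD contrast centered at
the mean; 0/1 treatments use the natural contrast. For linear outcomes
ACME = a·b·Δt (the Sobel product) and ACME + ADE = total effect exactly. For
binary outcomes, effects are computed on the probability (risk-difference)
scale by averaging potential-outcome probabilities over the mediator's
residual normal via 32-node Gauss–Hermite quadrature, averaging the two
treatment-arm decompositions so ACME + ADE = total also holds exactly;
a log-odds scale is available behind a flag. Proportion mediated =
ACME/total; as a ratio it can exceed 1 or blow up when the total effect is
near zero, which is why replicate-median summaries are used when reporting
it at the study's sample size.

Uncertainty: nonparametric bootstrap (subjects resampled with replacement,
default 10,000 resamples) with percentile intervals — the simplest faithful
reading of "nonparametric bootstrap" (no BCa correction). Bootstrap
resamples of a binary outcome containing a single class are redrawn and
counted. ACME/ADE p-values are two-sided sign-crossing fractions of the
bootstrap distribution.

## Problem sizes used by tests and the reproduction script

Phantoms: 32×12×12 to 36×36×12 voxels at 2.5 mm (tubes of 15–62 mm).
Monte-Carlo: 200 replicate cohorts (n = 97) for slope recovery, 500 for
type-I error, 100 synthetic triples for mediation-proportion recovery;
bootstrap sizes 200–2,000 in tests and 10,000 for the single full-size
mediation run in the reproduction script. These sizes are the package's own
accuracy/runtime trade-off and are trivially adjustable.

## Known limitations

- Deterministic single-tensor tracking cannot represent crossing or kissing
  fibers; phantoms avoid such configurations by construction.
- The local-efficiency variant and the mixed-model df rule are documented
  choices among several in field use; alternative conventions would shift
  absolute values slightly without affecting the pipeline's contracts.
- The simulated cohort is a linear Gaussian world; effect-size defaults are
  calibration anchors, not estimates with uncertainty.
- Proportion mediated is reported with its bootstrap interval precisely
  because its sampling distribution is heavy-tailed at n ≈ 100.
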