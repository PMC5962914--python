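# svdnet

Structural-network change and dementia risk in cerebral small vessel disease
(SVD): a tested, reusable re-implementation of the analysis pipeline linking
longitudinal decline in white-matter network **global efficiency** to incident
dementia and cognitive decline — exercised entirely on synthetic
diffusion-tensor phantoms and simulated longitudinal cohorts, so every stage
is verifiable against known ground truth without any patient data.

## Who this is for

Researchers in cerebrovascular imaging and vascular cognitive impairment who
want (a) a transparent reference implementation of the
tractography-to-mediation analysis chain, and (b) a simulation harness for
power analysis and methods validation of longitudinal connectome studies.

## What the pipeline computes

1. **Phantoms** (`svdnet.phantom`): 3-D grids of symmetric diffusion tensors
   (2.5 mm isotropic by default) with embedded fiber tubes, end-cap
   parcellation labels, and spherical SVD-like lesions that raise mean
   diffusivity (MD) and lower fractional anisotropy (FA).
2. **Tractography** (`svdnet.tracking`): deterministic tensorline tracking —
   seeds on a 0.5 mm super-resolution grid where FA ≥ 0.2, fixed 0.5 mm Euler
   steps along the interpolated principal eigenvector, termination at
   FA < 0.2 or turns > 45°, streamlines kept between 20 and 250 mm.
3. **Connectomes** (`svdnet.connectome`): for regions A, B the edge weight is

   w(A,B) = ½ · Σ over connecting streamlines of 1 / length(mm),

   with edges below weight 1 removed. Global efficiency is
   E_glob = (1/(n(n−1))) · Σ_{i≠j} 1/d(i,j) with edge lengths 1/w; edge
   count, mean edge weight, total strength and mean local efficiency are
   reported alongside.
4. **MD histogram** (`svdnet.histogram`): normalized peak height (NPH) — the
   fraction of white-matter voxels in the modal MD bin; lower NPH means more
   abnormal white matter.
5. **Cohort simulation** (`svdnet.cohortsim`): per-subject random
   intercepts/slopes for each imaging measure (efficiency baseline
   7.94 ± 2.30, mean decline −0.1764/yr), logistic dementia conversion driven
   by the efficiency slope (marginal rate 17.5%), correlated cognitive
   decline, Poisson lacune/microbleed accrual, visit jitter and dropout.
6. **Longitudinal models** (`svdnet.longmodels`): random intercept + slope
   mixed models `value ~ (1 + t | subject)`; the fixed slope is the group
   annualized change and per-subject totals (fixed + BLUP) feed the outcome
   models. Post-dementia MRI censoring and lesion-count dichotomization
   included.
7. **Outcome models** (`svdnet.outcomes`): single-predictor and
   forward-AIC-stepwise logistic (dementia) and linear (cognitive slope)
   regressions, VIF diagnostics, and the decline-tertile illustration.
8. **Mediation** (`svdnet.mediation`): ACME / ADE / total effect / proportion
   mediated with nonparametric bootstrap percentile intervals (10,000
   resamples by default); linear-linear ACME equals the Sobel product a·b.

## Worked example

```python
import pandas as pd
import svdnet as sv

# a 60 mm fiber tube in a 80x30x30 mm volume
cl = sv.StraightCenterline([10.1, 15, 15], [69.9, 15, 15])
tract = sv.TractSpec(cl, 2.2, 1.7e-3, 0.2e-3, endpoint_region_ids=(1, 2))
vol, parc = sv.make_tensor_phantom([tract], shape=(32, 12, 12), voxel_size_mm=2.5)

streams = sv.whole_volume_tractography(vol)
conn = sv.build_connectome(streams, parc)
print(len(streams), round(float(streams.lengths_mm.mean()), 2))
# 19832 59.99        <- ~125 seeds per tube voxel, tracked length ~ tube length

# a simulated cohort through the statistical chain
tab = sv.simulate_cohort(rng_seed=11)
eff = sv.fit_lmer_slopes(tab, "global_efficiency")
print(round(eff.fixed_slope, 4))
# -0.1794            <- group annualized decline in global efficiency

res = sv.fit_logistic_outcome(
    pd.DataFrame({"d_eglob": eff.subject_slopes}),
    tab.subjects["converted"])
print(res.coefficients.round(4))
#               B      se       p      OR
# d_eglob -1.0231  0.2951  0.0005  0.3595
```

The logistic row reads: one SD faster decline in network global efficiency
multiplies the odds of converting to dementia by ≈ 0.36 (equivalently, slower
decline is protective), echoing the strong negative association the method is
designed to detect.

A thin CLI mirrors the library (`svdnet phantom / track / connect / metrics /
nph / simulate-cohort / fit-longitudinal / fit-outcomes / mediate`); run
`svdnet --help`.

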