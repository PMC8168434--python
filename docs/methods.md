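# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `perfutex`.

## Signal model and relaxometry

The dynamic series is modelled as a steady-state spoiled gradient echo
(SPGR): S = M0 sin(α)(1−E)/(1−E cos α) with E = exp(−TR/T1). Default
acquisition constants describe a 3 T abdominal protocol — TR/TE 3.9/1.4 ms,
dynamic flip angle 12°, 40 frames at 6 s spacing (240 s), two pre-contrast
frames, 0.1 mmol/kg contrast dose. The multi-flip-angle baseline
acquisition defaults to {3°, 6°, 9°, 12°, 15°}; the protocol source does
not fix these angles, so they are configuration, as is the relaxivity
r1 = 4.3 s⁻¹(mmol/L)⁻¹ (a typical 3 T value for gadolinium agents; no
authoritative value exists for the software being emulated).

Baseline T1 is fitted from the linearised SPGR relation S/sin α = E·S/tan α
+ M0(1−E) by per-voxel least squares; slopes outside (0,1) (including
all-zero voxels) are flagged invalid rather than raising.

Two signal→concentration conversions are provided:

* **linear** (default, mirroring common commercial practice):
  C = (S − S0)/(S0 · r1 · T10), S0 = mean of the pre-contrast frames.
  Negative concentrations from noise are retained by default so baseline
  noise statistics stay unbiased (`clip_negative` to override).
* **exact**: closed-form inversion of the SPGR equation for T1(t), then
  C = (1/T1(t) − 1/T10)/r1. Signal ratios outside the invertible range are
  flagged per voxel/time.

A point worth knowing: the linear reduction is *not* asymptotically equal
to the exact inversion as C → 0. At short TR its low-concentration limit is
the exact answer times the sensitivity factor
TR·E(1−cos α)/[(1−E)(1−E cos α)·T10] ≈ 0.85 at the default protocol, and it
saturates further at high enhancement. Because the same factor applies to
tissue and artery it largely cancels in the kinetic-parameter ratios, which
is why the linear default is tenable; quantitative concentration work
should use `method="exact"`, and the recovery tests do.

## Arterial input function

The model input C_p is plasma concentration: the mean curve over the aorta
mask divided by (1 − hematocrit), default Hct 0.42. The correction is
applied even though clinical packages are often silent about it, because
the Tofts formulation is defined on plasma; setting `hematocrit=0` disables
it. The mean (not median) over hand-picked aorta voxels is used, with no
automatic vessel detection, partial-volume or inflow correction.

## Extended Tofts fitting

C_t(t) = v_p·C_p(t) + K^trans ∫ C_p(τ)e^{−k_ep(t−τ)}dτ, integrated by
causal trapezoidal quadrature on the sampling grid (times converted to
minutes internally; parameters are reported in min⁻¹). The fit is bounded
nonlinear least squares in (K^trans, k_ep, v_p) — bounds [0,5], (0,10],
[0,0.5] — initialised from the linear matrix formulation
C = (K^trans + k_ep v_p)∫C_p − k_ep∫C_t + v_p C_p, which is also exposed as
a fast linear-only mode. v_e is K^trans/k_ep by construction. Bolus arrival
is taken from the AIF; no per-voxel onset is fitted, because a 6 s frame
spacing makes onset estimation ill-posed. Solver failure or a solution
pinned at an upper bound yields `fit_ok = False` (never silent zeros); an
all-zero curve is the legitimate no-uptake case and returns K^trans = 0
with an unidentifiable k_ep reported as 1.0 by convention. ROI summaries
average over `fit_ok` voxels only.

## Texture

Parameter maps (K^trans by default) are min–max quantized to 32 equal-width
levels inside the mask (affine-invariant; constant maps collapse to one
level). Co-occurrences are counted over the 13 unique 3D directions at
distance 1, pooled into a single symmetric matrix and normalized — pooling
rather than per-direction feature averaging is the convention of several
radiomics engines, and both the level count and distance are configurable.
Entropy uses log base 2 (bits), consistent with entropy magnitudes in the
5–7 range at 32 levels; the base is configurable. Correlation is reported
as missing (NaN) when a marginal is degenerate.

## The synthetic cohort generator

The phantom emulates a two-visit (pre/post treatment) study with 16 CR and
16 PR patients by default. Per lesion:

* the lesion-level mean of each kinetic parameter is drawn from a truncated
  normal whose mean/SD are the published group moments for that visit and
  class (e.g. post-treatment K^trans 0.117 ± 0.065 min⁻¹ for CR vs
  0.299 ± 0.231 for PR; v_e 0.130 ± 0.094 vs 0.322 ± 0.204; v_p near
  0.003–0.004). The published SDs are between-patient SDs of ROI means, so
  they are applied at the lesion level; voxels vary around the lesion mean
  multiplicatively. Drawing voxels independently from the group moments
  instead would shrink the between-patient variance by 1/√n_voxels and
  make every group contrast trivially significant.
* voxelwise heterogeneity is a spatially correlated multiplicative Gaussian
  field (CV 0.3) whose roughness is a per-lesion mixing weight
  w ~ Beta(a,b) between a smooth (σ = 2.5 voxels) and a fine-grained
  (σ = 0.45 voxels) component. Both classes share Beta(1.5, 6) before
  treatment (pre-treatment texture does not separate responders); after
  treatment CR draws Beta(2, 4) and PR Beta(4, 2), so lesions roughen under
  treatment in both classes and PR lesions end up with higher co-occurrence
  entropy, with a standardized class separation of about one pooled SD —
  the effect size seen in patients.
* k_ep is derived as K^trans/v_e.

The forward model composes the Tofts convolution, 1/T1(t) = 1/T10 + r1·C,
and the SPGR equation (tissue T10 = 1.0 s, blood 1.6 s, typical 3 T
values). Cohorts written to disk include, per visit, the 4D dynamic series,
a 4D multi-flip-angle baseline stack, lesion and aorta masks (NIfTI-1), a
manifest CSV with the true lesion means, and the population AIF. Noise is
additive Gaussian on the signal, default SD 2% of the pre-contrast lesion
signal (high-SNR magnitude MRI is approximately Gaussian); a Rician option
was considered out of scope. Everything is deterministic per seed.

The population AIF is a closed-form curve: a gamma-variate first-pass bolus
(amplitude 4.5 mmol/L, time-to-peak 0.6 min) over a dose-scaled
biexponential washout (amplitudes 3.99 and 4.78 (mmol/L)/(mmol/kg), decay
rates 0.144 and 0.0111 min⁻¹ — classic plasma-clearance constants) with a
smooth upslope, injected at the end of the pre-contrast frames. The bolus
is deliberately broad enough that 6 s sampling resolves it (trapezoidal
area within 1% of fine-grid quadrature): a measured aorta curve at this
frame rate cannot look sharper.

### What the phantom does and does not show

The generator reproduces the *between-class contrasts* (direction and
standardized effect size) of the kinetic and entropy markers, so passing
the cohort-level tests demonstrates that the estimation and statistics
chain preserves real effect sizes at n = 16+16 — not that the package
reproduces any particular patient cohort. Absolute GLCM entropy values are
higher in the phantom (~8.3 vs ~6.1–6.8 bits) because phantom lesions are
only ~11 voxels across: with 32 levels, even a smooth full-range field
steps ≥2 levels per voxel at that size, which floors the entropy.
Matching absolute entropy would require lesions ~30 voxels across and a
corresponding 30–50× increase in voxelwise fitting cost; the standardized
separation, which is what the statistics consume, is matched instead. The
phantom also omits motion, B1 inhomogeneity, slice-profile and k-space
effects, variable lesion size/shape, and any correlation between kinetic
level and texture class.

## Statistics

* **Group tests**: two-sided Mann–Whitney U; exact enumeration when
  n₁+n₂ ≤ 12 without ties, otherwise the tie- and continuity-corrected
  normal approximation. A constant pooled sample returns p = 1 with a
  warning. No multiple-testing correction is applied across the feature
  tests, mirroring the analysis style being implemented (a
  Benjamini–Hochberg pass would be a one-line addition upstream of the
  filter).
* **Redundancy filter**: candidates with p < 0.05 are visited in
  ascending-p order and dropped if |Spearman ρ| ≥ 0.6 against any retained
  feature. Retaining the smallest-p member is a choice the filter rule
  itself does not determine; it is the greedy convention.
* **Logistic model**: CR is the positive class, so markers that fall under
  effective treatment get negative coefficients. The MLE is IRLS/Newton
  (via statsmodels); Wald = (coef/SE)², OR = exp(coef), 95% CI =
  exp(coef ± 1.96·SE). At n = 32 complete separation happens; it is flagged
  and the capped-IRLS iterate is reported with a warning, never silently.
  The published combined-model coefficients ship as the named preset
  `EQ4_MODEL_POST` for `predict_prob`.
* **ROC**: AUC by the rank formulation (ties half credit), which equals
  U/(n₁n₂) identically; cutoff maximizes Youden's J with ties broken toward
  higher sensitivity; CIs from DeLong structural components. Single-feature
  ROC direction is chosen so AUC ≥ 0.5 (the convention of standard ROC
  packages). Model variants built from post-only, change-only, and pooled
  candidate sets are compared pairwise with the paired DeLong test;
  degenerate variance returns p = 1 with a warning.

## Numerical and interface choices

* Time integration in minutes; NIfTI-1 for all volumes; masks must match
  their image's grid and affine within 1e-4 — no resampling is performed,
  per-visit volumes are assumed co-registered.
* The pipeline runner fingerprints stage inputs and outputs (SHA-256) in
  `state.json`; a rerun skips unchanged stages, and a corrupted
  intermediate re-runs only itself and its downstream stages.
* Default test/replicate problem sizes (11×11×7 lesions, 200 replicate
  cohorts, 500-voxel noise studies) were chosen to characterize the
  estimators well while keeping a full run in minutes on a single core.

## Known limitations

* One lesion per patient; no Patlak/2CXM/reference-region alternatives; no
  spatial regularization of fits; no cross-validation in the statistics
  stage (the implemented analysis style uses apparent performance, which
  is optimistic — the replicate-level tests quantify that optimism).
* The linear conversion bias discussed above is inherent to the
  signal-ratio formula, not an implementation artifact.
* B1/flip-angle miscalibration and T2* effects are not modelled; VFA T1
  accuracy claims hold for the idealized SPGR signal.
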