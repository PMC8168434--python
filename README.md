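# perfutex

Quantitative DCE-MRI analysis for treatment-response assessment: voxelwise
extended Tofts pharmacokinetic mapping, 3D gray-level co-occurrence texture
features, and the group-comparison → redundancy-filter → logistic-model →
ROC statistics chain used to separate complete (CR) from partial (PR)
pathological responders to neoadjuvant chemoradiotherapy — exercised
end-to-end on a synthetic DCE-MRI phantom cohort with known ground truth.

It is written for imaging scientists who want a tested, reproducible
reference implementation of this analysis style — from raw 4D dynamic
signal to the final odds-ratio and AUC tables — without access to patient
data.

## The model

A spoiled gradient echo at steady state gives signal

    S = M0 sin(α) (1 − E) / (1 − E cos α),    E = exp(−TR / T1),

from which baseline T1 (T10) is mapped with the variable-flip-angle method
and contrast concentration follows from the change in relaxation rate,
C(t) = (1/T1(t) − 1/T10) / r1 (linear signal-ratio reduction by default,
exact SPGR inversion by flag). Tissue kinetics follow the extended Tofts
model,

    C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^{−k_ep (t−τ)} dτ,

fitted per voxel by bounded nonlinear least squares (linear-system
initialisation), with v_e = K^trans / k_ep. The arterial input C_p comes
from an aorta region with hematocrit correction. Lesion texture is the
seven Haralick-type features (energy, entropy, inertia, correlation,
cluster shade, cluster prominence, inverse difference moment) of a pooled
13-direction 3D co-occurrence matrix at 32 gray levels. The statistics
stage runs Mann–Whitney U per feature, drops redundant features at
|Spearman ρ| ≥ 0.6 (keeping the smallest-p member), fits a logistic model
on the retained set, and reports Wald statistics, odds ratios, ROC
AUC/Youden cutoffs with DeLong confidence intervals, and paired DeLong
model comparisons.

## Worked example

```python
from perfutex.phantom import make_lesion_table
from perfutex.stats import run_full_analysis

table = make_lesion_table(n_cr=16, n_pr=16, seed=7)   # two visits/patient
report = run_full_analysis(table)

for f in ("ktrans_post", "ve_post", "entropy_post"):
    t = report["group_tests"][f]
    print(f, t.u_statistic, round(t.p_value, 4), round(report["roc_single"][f].auc, 3))
print("combined AUC:", report["combined_roc"].auc)
```

prints

```
ktrans_post 28.0 0.0002 0.891
ve_post 58.0 0.0088 0.773
entropy_post 51.0 0.0039 0.801
combined AUC: 1.0
```

Each line is one post-treatment marker: the Mann–Whitney U statistic and
two-sided p-value for the CR-vs-PR contrast over the 16+16 synthetic
patients, and the single-feature ROC AUC. All three markers separate the
groups (higher K^trans, v_e and entropy in non-responders), and the
combined logistic model separates this particular cohort perfectly —
small-cohort AUCs are optimistic, which is why the test suite judges the
combined model over hundreds of replicate cohorts rather than one.

The same analysis can start from images instead of a feature table:

```sh
perfutex run-all --seed 7 --out run/     # simulate → T1 map → concentration
                                         # → AIF → Tofts fit → texture →
                                         # features → statistics
```

which writes NIfTI parameter maps, `features.csv`, printable CSV tables
and `report.json` under `run/`.

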