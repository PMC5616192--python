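# tbikit

Quantitative MRI and histology markers of traumatic axonal injury, on
synthetic data.

Diffuse axonal injury — the widespread mechanical damage to myelinated
axons that follows closed-head trauma — is visible to diffusion tensor
imaging (DTI) even when conventional structural MRI looks normal.
Evaluating *which* DTI metrics and brain regions carry that signal
requires a full analysis chain: tensor estimation from multi-shell
diffusion-weighted images, scalar metric maps, voxelwise group
difference maps, per-region statistics with multiple-comparison
correction, quantitative immunohistochemistry, and a classifier that
ranks regions and metrics by diagnostic value. `tbikit` implements that
chain end to end for a two-group design (n = 5 sham vs n = 5 injured),
together with the synthetic phantoms, photomicrographs and cohorts
needed to exercise and calibrate every stage.

It is aimed at methods developers who need a controlled test bed for
small-cohort DTI group analyses: every input is simulated with known
ground truth, every statistical property is testable.

## The core quantities

Per voxel, the diffusion tensor D (mm²/s) is fitted from
S_i = S0·exp(−b_i ĝ_iᵀ D ĝ_i) by weighted log-linear least squares
followed by nonlinear refinement. From sorted eigenvalues
λ1 ≥ λ2 ≥ λ3:

* FA (fractional anisotropy), T = λ1+λ2+λ3 (trace), AD = λ1,
  RD = (λ2+λ3)/2;
* Westin shape measures WL = (λ1−λ2)/T and WP = 2(λ2−λ3)/T
  (trace-normalised, so WL + WP + 3λ3/T = 1; a λ1-normalised convention
  is selectable).

Per region and metric, groups are compared with pooled-variance
two-sample t tests (df = 8), corrected within each 19-region family by
the Holm-Šidák step-down rule p̃(i) = max_{j≤i} 1 − (1−p(j))^(m−j+1).
Injury classification uses a Breiman random forest (2000 unpruned
Gini trees, m_try = ⌊√F⌋, bootstrap n-with-replacement) evaluated by
out-of-bag (OOB) votes, with permutation-based mean-decrease-accuracy
feature importances.

## Worked example

Build a cohort whose effect sizes are calibrated from published
two-sample t statistics (d = t·√0.4), test one metric family, and
classify:

```python
from tbikit.cohort import CohortSpec, make_feature_cohort
from tbikit.datasets import dti_effect_sizes
from tbikit.roistats import table_analysis, results_frame
from tbikit.classify import RFConfig, rf_classify, rank_rois

cohort = make_feature_cohort(
    CohortSpec.from_effect_frame(dti_effect_sizes(), seed=0))
res = results_frame(table_analysis(cohort, "WL"))
print(res.sort_values("p_adj").head(4).to_string(index=False))

report = rf_classify(cohort, config=RFConfig(seed=0))
print(report.summary())
print(rank_rois(report).to_string(index=False))
```

Output:

```
              roi metric        t  df        p    p_adj  family_size flags
Optic Tract_Right     WL 5.682113   8 0.000464 0.008777           19    #*
 Hippocampus_Left     WL 4.034010   8 0.003767 0.065678           19     #
    Brachium_Left     WL 3.429584   8 0.008960 0.141881           19     #
Hippocampus_Right     WL 3.287476   8 0.011064 0.163061           19     #

Random-forest OOB report
========================
injured    correct   5  incorrect   0  error 0.00
sham       correct   5  incorrect   0  error 0.00
overall error 0.00 (accuracy 1.00)
top features by scaled MDA:
  Optic Tract_Right_WP                        5.569
  Optic Tract_Right_WL                        5.505
  Optic Tract_Left_AD                         5.475
  Internal Capsule_Right_RD                   5.427
  Optic Tract_Right_RD                        5.413

                   roi    score      associated_metrics
     Optic Tract_Right 5.568942 [WP, WL, RD, T, AD, FA]
      Optic Tract_Left 5.474995            [AD, WP, FA]
Internal Capsule_Right 5.426897        [RD, AD, WP, FA]
```

Reading it: in this draw the right optic tract's linear anisotropy
survives family-wise correction (`*`, adjusted p ≈ 0.009), three further
regions are raw-significant only (`#`), the forest separates the ten
samples perfectly out-of-bag, and the regions ranked most important for
classification are dominated by the optic tract — the region carrying
the largest injected effects.

The same chain is scriptable from the shell:

```sh
tbikit run --seed 1 --out study/          # full pipeline, one seed
tbikit roistats --features study/dti_cohort.csv --family FA --out fa.csv
tbikit classify --features study/dti_cohort.csv --trees 2000 --out rf/
```

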