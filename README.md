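# dermgfr

Non-invasive chronic-kidney-disease (CKD) assessment from forearm skin
texture.

Creatinine-based eGFR equations (MDRD, CKD-EPI) carry a two-valued race
multiplier, which fits poorly for populations that are neither of the two
reference groups. `dermgfr` implements an alternative: CKD alters skin
hydration and collagen, which shows up as denser, deeper wrinkle lines, so
a continuous per-subject "skin parameter" S_p can be read off a forearm
photograph and substituted for the race factor. The package is aimed at
biomedical-imaging researchers who want to reproduce, probe or extend this
texture-based eGFR pipeline.

The chain: morphological top-hat enhancement → directional gradient
(gx = ∂f/∂x, gy = ∂f/∂y, θ = atan2(gy, gx)) → grey-level co-occurrence
matrix (GLCM) → four Haralick texture random variables (contrast,
correlation, energy, homogeneity, all on a [0, 1] scale, plus entropy) →
four-parameter logistic collapse at the subject's age x,

    S_p = d + (a − d) / (1 + (x/c)^b),      a = contrast, b = energy,
                                            c = correlation, d = homogeneity

→ texture-based eGFR

    GFR = 175 · Scr^−1.154 · age^−0.203 · S_p      [ml/min/1.73 m²]

→ staging (≥90 → 1, 60–89 → 2, 30–59 → 3, 15–29 → 4, <15 → 5). On top of
that sit per-level ensemble statistics (mean ± SD of each subject's
mean-of-RVs, percent deviation from the level-1 baseline) and two small
feed-forward classifiers (5-5-5 with serum creatinine; 7-5-5 with texture
inputs and **no** creatinine). Because no patient data are deposited, a
synthetic-data module generates stage-conditioned cohorts and wrinkle
images that make every stage testable; see `docs/methods.md` for the model
and its limits.

## Worked example

```python
import dermgfr as d
from dermgfr.ensemble import summarize_levels, summary_frame

cohort = d.generate_labelled_cohort(d.CohortConfig(seed=0))
print(summary_frame(summarize_levels(cohort)).round(4).to_string(index=False))
```

```
 level  mean_of_process     sd  deviation_pct  n
     1           0.5607 0.0232            NaN 11
     2           0.4826 0.0194        13.9307 16
     3           0.4196 0.0137        25.1694 16
     4           0.3765 0.0139        32.8529 16
     5           0.3360 0.0119        40.0759 16
```

Each row is one CKD level of the 75-subject synthetic cohort (11 normal,
16 per level 2–5): the ensemble mean of the subjects' mean-of-RVs falls
monotonically with stage — sicker skin is rougher skin — and the last
column is the percent deviation from the normal (level-1) baseline. One
subject through the eGFR equations:

```python
rec = cohort[0]          # age 49.4, level 1 (normal), Sp 0.887
g = d.GFRInputs(scr=rec.scr_mg_dl, age=rec.age, sp=rec.sp)
d.mdrd_gfr(g)            # GFRResult(value=127.96..., method='MDRD', level=1)
d.proposed_gfr(g)        # GFRResult(value=113.49..., method='proposed', level=1)
```

The texture equation agrees with MDRD on the stage (here level 1) while
using the subject's own S_p = 0.887 instead of a race constant. The
creatinine-free classifier on a held-out 30-subject test set (5 normals):

```python
from dermgfr import classifier as C
train, test = d.split_train_test(cohort, seed=0)
net = C.train(C.NetworkSpec(n_inputs=7),
              C.record_inputs(train, C.NETWORK2_INPUTS),
              [r.level for r in train], seed=0)
C.evaluate(net, C.record_inputs(test, C.NETWORK2_INPUTS),
           [r.level for r in test])
# TP 83.33%  TN 13.33%  FP 3.33%  FN 0.00%   -> 96.7% binary accuracy
```

The same flows are available from the shell:

```sh
dermgfr simulate --out cohort_dir --seed 0      # cohort.csv + skin PNGs
dermgfr gfr --scr 1.8 --age 55 --method mdrd    # MDRD GFR = 39.37 ..., level 3
dermgfr pipeline --cohort cohort_dir/cohort.csv --out results.csv
dermgfr train --network 2 --cohort cohort_dir/cohort.csv --seed 0 --out w.json
dermgfr evaluate --weights w.json --cohort cohort_dir/cohort.csv
```

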