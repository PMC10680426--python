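# rectdvh

Does the way you define the rectal contour and its dose-volume histogram
(DVH) change how well rectal dose predicts late gastrointestinal toxicity
after prostate radiotherapy?

Treatment plans are routinely optimised against *whole-rectum
relative-volume* (%) DVH constraints computed from the contour drawn at
the treating centre. Three plausible "improvements" are often proposed:
central review of the contour, absolute-volume (cc) DVH metrics, and
truncation of the open-ended rectum to the cranio-caudal extent of the
planning target volume (PTV ± 0 cm or PTV ± 2 cm). `rectdvh` implements
the full comparison pipeline needed to test whether any of these
alternatives actually predicts toxicity better, and ships a synthetic
cohort generator so the whole analysis is reproducible without access to
any trial data.

The package is aimed at radiotherapy outcome modellers and biostatisticians:
it is equally usable on synthetic cohorts (method validation, power
exploration) and on your own precomputed covariate tables (`stats-only`
mode).

## What it computes

**Dosimetry.** Cumulative DVHs (relative % and absolute cc) from a voxel
dose grid and structure mask. Dose levels of interest are defined at
2 Gy/fraction (V30, V40, V50, V60, V65, V70, V74 Gy) and mapped onto
hypofractionated regimens (60 Gy/20 Fr, 57 Gy/19 Fr) via the
linear-quadratic equivalent dose in 2 Gy fractions,

    EQD2(D, n) = D · (D/n + α/β) / (2 + α/β),   α/β = 3 Gy,

by inverting the map per level (physical dose whose EQD2 equals the
reference level), e.g. V74* for the 20-fraction arm sits at 61.10 Gy
physical dose.

**Geometry.** PTV-based truncation by slice-centre membership,
cranio-caudal length, volume, and the Dice similarity coefficient between
original and reviewed contours.

**Endpoints.** Eight binary late-toxicity endpoints (stool frequency
G1+/G2+, rectal bleeding G1+/G2+, proctitis G1+/G2+, sphincter control
G1+, stricture/ulcer G1+) derived from graded visits at months 0 and
6–60: nonzero baseline excludes the patient for that endpoint; any late
event scores toxicity; controls need ≥ 4 of 7 late visits completed.

**Statistics.** For each endpoint, the 7 dose-bin covariates are fitted
simultaneously in a logistic model (IRLS). Definitions are compared
pairwise by the DeLong paired AUC test; AUC 95% CIs come from stratified
bootstrap resampling and operating-point metrics (sensitivity,
specificity, PPV, NPV at the Youden point) from the .632 bootstrap.
Per-dose-level volume differences use the Wilcoxon signed-rank test
(exact for n ≤ 25). The 32 primary model comparisons are interpreted at
the Bonferroni-corrected .0015 level, exploratory dose-level tests at
.0001.

## Worked example

Simulate a 600-patient cohort across the three fractionation arms and
compare the standard-of-care definition against all three alternatives
for two endpoints:

```bash
cat > cohort.yaml <<EOF
n_patients: 600
seed: 3
EOF
rectdvh run --config cohort.yaml --seed 3 -B 200 \
    --endpoints bleeding_g1plus,proctitis_g1plus --outdir report/
```

`report/comparisons.csv` (abridged):

```
endpoint          definition_a        definition_b          n  auc_a  auc_ci_lo_a  auc_ci_hi_a  auc_b  delong_p
bleeding_g1plus   original_whole_rel  reviewed_whole_rel  546  0.629  0.602        0.714        0.635  0.589
bleeding_g1plus   original_whole_rel  original_whole_abs  546  0.629  0.599        0.711        0.634  0.681
bleeding_g1plus   original_whole_rel  original_ptv2_rel   546  0.629  0.588        0.717        0.631  0.557
bleeding_g1plus   original_whole_rel  original_ptv0_rel   546  0.629  0.587        0.709        0.633  0.773
```

Read: with 546 analysable patients (54 of 600 excluded for baseline
symptoms or insufficient follow-up), the whole-rectum relative-volume
model discriminates bleeding G1+ with AUC 0.63 — a weak but real
predictor (bootstrap CI above 0.5) — and none of the three alternative
definitions differs significantly from it (all DeLong p ≫ .0015). The
same run writes `morphology.csv` (median length 10.0 cm, volume 69.5 cc,
original-vs-reviewed Dice 0.97), the per-level Wilcoxon table (here V30*
differed directionally, p = 2.2e-5, significant at the exploratory .0001
level — small systematic contour differences that do *not* translate into
prediction differences), the EQD2 dose-level map, covariate and outcome
tables, and a CONSORT-style exclusion account.

The same comparisons run on your own data from a long-format covariate
CSV plus an outcome status matrix via `rectdvh stats-only`.

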