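# Methods

## The question and the analysis design

The package compares rectal DVH *definitions*, not models: the same
logistic NTCP model (7 dose-bin covariates, no variable selection) is
fitted per toxicity endpoint under each definition, and the definitions
are compared by the discrimination (ROC AUC) of the resulting models on
the same patients. Because the scores are paired, the DeLong test is the
appropriate comparison: it estimates the covariance of the two correlated
AUCs from midrank structural components and tests the difference with a
normal z statistic. Four hypotheses are evaluated, each against the
standard of care (whole rectum, original contour, relative volumes):
contour review, absolute volumes, truncation at PTV ± 2 cm, truncation at
PTV ± 0 cm. Eight endpoints × four hypotheses give 32 primary tests,
interpreted at the Bonferroni level floor(0.05/32, 4 dp) = .0015;
per-dose-level Wilcoxon comparisons are exploratory at .0001.

## Dosimetry

DVHs are cumulative and computed exactly at bin edges (0.1 Gy default
spacing; values at edges are exact voxel counts, interpolation is linear
between edges, so the 0.1 Gy grid only matters for queries strictly
between edges). Relative and absolute curves are linked by
`cum_abs = cum_rel × total_volume / 100` identically.

Fractionation is harmonised by *remapping query levels*, not by
transforming the dose grid: each 2 Gy/Fr reference level L is replaced,
for an n-fraction arm, by the positive root of `D²/n + (α/β)D =
L(2 + α/β)` (α/β = 3 Gy), evaluated in the cancellation-free form
`2c/(α/β + sqrt((α/β)² + 4c/n))`. This keeps each patient's physical DVH
untouched and reproduces the "EQD2-equivalent dose levels" construction.
Note the map's fixed point is dose/fraction = 2 Gy (D = 2n): levels above
38 Gy (19 Fr) or 40 Gy (20 Fr) map downward, lower levels map *upward*
(V30 → 32.0 Gy for the 19-Fr arm). Seven levels including V65* are the
modelling default; the six-level constraint-style set is available via
the `levels` option.

## Geometry

Truncation keeps whole slices whose centre z lies in the closed interval
`[PTV_inf − margin, PTV_sup + margin]`; in-plane voxels are never edited.
Length is the occupied-slice span × dz (a one-slice organ has length dz),
volume is voxel count × voxel volume, and Dice is `2|A∩B|/(|A|+|B|)`.
Structures that are empty after truncation are excluded from DVH stages
with a logged reason that enters the CONSORT accounting.

## Endpoint derivation

Grades are on a unified 0–2 scale (1 = event without intervention,
2 = with intervention; anything above 2 is treated as ≥ 2). Per
patient-endpoint: baseline grade ≥ 1 → excluded; else any late visit at
or above threshold → case; else control if ≥ 4 of the 7 late visits
(months 6–60) were completed; else excluded for insufficient follow-up.
A completed visit is any visit with a recorded grade including 0 —
completeness is attendance, not symptoms. A missing baseline row is
treated as grade 0 (counted in the log); the alternative (exclusion) was
rejected because attendance-based exclusion is already handled by the
follow-up rule and a missing baseline row in practice reflects data
assembly, not symptoms.

## Statistical engine

*Logistic fits* use IRLS with convergence at max |Δβ| < 1e-8 or 100
iterations; non-convergence is flagged (it almost always signals
separation) and such fits are skipped inside bootstrap loops.
Zero-variance covariates — which arise structurally, e.g. V74* is
identically 0 in hypofractionated arms because the mapped level exceeds
the prescription — are dropped from the design with slope pinned at 0, so
per-arm sensitivity analyses cannot produce singular normal equations.

*AUC* is the midrank Mann-Whitney statistic. *Bootstrap*: cases and
controls are resampled with replacement separately, preserving counts
("stratified by toxicity"); the AUC point estimate is the full-sample
fit, the CI the 2.5th/97.5th centiles of per-resample refit AUCs. Because
per-resample AUCs are apparent (in-sample) values, they carry the same
optimism as the point estimate; at small n the CI can sit asymmetrically
around the point estimate (a flag records when it fails to bracket it).
*Operating-point metrics* use Youden's J on the fitting sample (ties
broken toward the lower threshold; exact integer arithmetic so ties are
real ties) — the fixed-0.5 rule is selectable — and are reported as .632
estimates: `0.368 × apparent + 0.632 × mean out-of-bag`. The .632+
variant is deliberately not implemented. PPV/NPV are computed at the
evaluation set's observed prevalence.

*Wilcoxon signed-rank*: zeros dropped, midranks on |differences|; for
n ≤ 25 the null distribution of the (doubled, hence integer) positive
rank sum is enumerated exactly by subset-sum dynamic programming; beyond
that a tie-corrected normal approximation with continuity correction is
used.

*Seeding*: one master seed; per-(endpoint, definition-pair) substreams
are keyed on the *global* identity of the endpoint and definitions, so a
model's results are identical whether it is run alone or as part of the
full grid.

## Synthetic cohorts

The generator produces the study conditions the analysis assumes, not
anatomically realistic patients:

- **Geometry.** Rectum = stack of filled circles along z (in-plane 0.2 cm,
  dz 0.5 cm; length ~ N(9.5, 1.5) cm, radius ~ N(1.5, 0.15) cm), PTV = a
  box abutting and slightly overlapping the anterior wall (z-extent
  ~ N(7.0, 0.8) cm, overlap depth ~ N(0.4, 0.1) cm), with the rectum
  extending ~1 cm below and a few cm above the PTV. These values put the
  morphology table in the clinically familiar range (median length
  ≈ 10 cm, volume ≈ 65–70 cc, PTV ± 0 length ≈ 7 cm).
- **Dose.** Prescription inside the PTV, exponential decay with Euclidean
  distance from the PTV surface (scale 2.0 cm). The cap at prescription
  means hypofractionated arms have exactly zero volume at mapped levels
  above their prescription — real plans would show small hotspot volumes
  there; the fitter's zero-variance handling absorbs this.
- **Contour review.** The "reviewed" contour re-draws the superior border
  with probability 0.43 and the inferior with 0.32 (the reported
  border-change rates); the shift magnitude is uniform on 1–3 slices
  (0.5–1.5 cm), extension or removal equally likely, extension copying
  the terminal cross-section. Magnitudes are a modelling choice (no
  distributional detail exists to emulate) chosen to match reported
  length-difference IQRs of roughly 0–1.5 cm.
- **Toxicity.** Per symptom, the G1+ event probability is
  expit(β₀ + Σβₖxₖ) on the patient's true whole-rectum relative
  covariates, with defaults β = (−2.2, 0, 0, 2.0, 0, 0, 0, 8.0) plus
  per-symptom intercept shifts (frequency +0.4 … stricture/ulcer −2.4)
  and a −1.4 logit offset for G2+. A single latent uniform nests G2+
  events inside G1+ events. These defaults put prevalences at ~2–25% and
  model AUCs in the weak-predictor regime (≈ 0.57–0.67) that the analysis
  is designed around. Visits are completed independently with
  probability 0.85; when an event is drawn, one uniformly chosen visit is
  forced complete and records the maximum grade, so the record-level
  event rate equals the model probability exactly. Baseline G1+ occurs
  independently with probability 0.10. Endpoints are simulated without
  cross-symptom correlation, matching the per-endpoint analysis.

What the generator does **not** emulate: anatomical deformation,
bladder/bowel structures, planning-system optimisation, delivered-dose
variation, correlated symptom clusters, or informative (outcome-dependent)
missingness of follow-up. Passing tests therefore demonstrate that the
*pipeline machinery* is correct and calibrated under its stated model;
they do not validate clinical conclusions on real plans.

A fast slice-profile covariate sampler (`sample_covariates`) mirrors the
voxel generator semi-analytically (same geometry distributions, circular
segment coverage per slice, plus 5% lognormal per-level jitter standing
in for residual contouring variability and keeping the 7 bins full rank).
It exists for harnesses that need hundreds of thousands of patients —
Wald-coverage recovery at n = 20 000 × 20 repetitions — where voxel
cohorts would be needlessly slow.

## Validation harnesses and problem sizes

The self-validation suite (also run by `scripts/acceptance.py`) uses:
type-I error of the paired DeLong test from 1000 simulated nulls at
n = 200 (two equally noisy derivatives of one signal); Wald coverage
pooled over 20 × 8 (repetition, coefficient) pairs at n = 20 000;
percentile-bootstrap CI coverage from 100 repetitions at n = 500,
B = 500 using a *prespecified* score — a refitted multi-covariate model's
apparent AUC is optimism-biased by construction, so CI coverage of the
null is only a meaningful check without refitting; and the headline
four-hypothesis grid on a 2000-patient cohort with B = 200 (the package
default for production runs is B = 2000; B = 200 gives CI endpoints
stable to ~0.01 at these sample sizes and keeps the reproduction script
in minutes).

## Known limitations

- The voxel lattice is coarse (0.2/0.5 cm); lengths and volumes are exact
  on the lattice but quantised relative to continuous anatomy.
- The dose model has no hotspots and no in-plane anisotropy beyond
  distance-to-PTV, so absolute-volume and relative-volume covariates are
  more strongly coupled than in real plans.
- The bootstrap AUC CI inherits in-sample optimism (see above); the .632
  machinery corrects the operating-point metrics but no optimism
  correction is applied to the AUC itself, mirroring the analysis being
  reproduced.
- `stats-only` mode requires both definitions' covariates for every
  patient; no imputation is attempted.
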