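# Methods

This note documents the models, conventions and numerical choices behind
`wmfc`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and where the design was
genuinely open.

## Functional correlation matrices

Functional connectivity (FC) between two regions is the Pearson
correlation of their mean BOLD time courses.  Region order and membership
come from a packaged registry of 48 white-matter tracts (21 per hemisphere
plus 6 commissural/midline, Eve-atlas parcellation) and 82 gray-matter
regions (41 Brodmann areas per hemisphere).  Per subject, the all-ROI
correlation matrix is cut into three labelled blocks:

- `FCM_WG` — WM tract x GM region, 48 x 82 = 3,936 elements;
- `FCM_WW` — WM x WM, 48 x 48 (1,128 unique off-diagonal pairs);
- `FCM_GG` — GM x GM, 82 x 82, computed only as a comparison baseline.

The 3,936 WG elements plus the 1,128 unique WW elements give the 5,064 WM
FC features used by the machine-learning stages.

**Motion censoring.**  Framewise displacement is
`FD(t) = Σ|Δtrans_i| + 50 mm · Σ|Δrot_i|` (backward differences, rotations
in radians converted on a 50 mm sphere), with `FD(0) = 0`.  Correlations
are computed on exactly the frames with `FD ≤ 0.5 mm`; a subject retaining
fewer than 10 frames (configurable floor) is excluded with a logged
reason.  The censored correlation equals textbook Pearson on the
physically truncated series — this equivalence is enforced by an oracle
test at 1e-12.

**Covariate partialling.**  Across subjects, each FCM element is
residualized by OLS on age, sex, years of education and dummy-encoded
acquisition site (reference level dropped; collinear columns dropped with
a warning).  The residual is returned plus the element's grand mean so
group means stay interpretable on the correlation scale.  Residualized
values may leave [-1, 1] and are deliberately not re-clipped.  No Fisher
z-transform is applied anywhere by default (raw coefficients are averaged
and tested); `fisher_z` exists for users who want it.

**Temporal cleaning (optional stage, image path).**  Voxel signals are
detrended and nuisance-regressed in a single OLS projection (intercept,
linear ramp, Friston 24-parameter motion expansion — the 6 rigid-body
parameters, their one-frame lags, and both sets squared — plus mean CSF
signal), then band-passed 0.01-0.1 Hz with a zero-phase forward-backward
Butterworth filter (order 4 per pass), then z-normalized per voxel.
Folding the detrend into the projection makes the detrend+regression step
exactly idempotent, which the filter (a smoother, not a projection) is
not.  ROI means are re-z-normalized after averaging, an interpretation
choice: averaging z-scored voxels does not itself yield unit variance.
Upstream spatial preprocessing (realignment, normalization, segmentation)
is out of scope; the package consumes MNI-space data.

## Group statistics

For each CN-vs-patient contrast, the element-wise statistic is the
difference of group means.  Significance comes from a two-sided label
permutation test (default 10,000 permutations) in which each label shuffle
is shared across all elements, preserving their dependence;
`p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1)`, so p is never zero and the
test is valid (slightly conservative).  Multiplicity is controlled with
Benjamini-Hochberg FDR over the whole matrix (one family per matrix per
contrast); display matrices zero the elements with adjusted p > 0.05.
Effect sizes are Cohen's d with pooled SD.  Note a resolution interaction:
with 10,000 permutations the smallest attainable p is ~1e-4, while the BH
threshold for a single isolated discovery among 3,936 tests is ~1.3e-5 —
isolated effects cannot survive FDR; recovery therefore requires (and the
validation studies plant) multiple affected elements.

WM-tract-wise FC averages a tract's row of the WG matrix (82 elements) or
of the WW matrix; for WW the self-correlation diagonal is excluded by
default, since the constant 1 would bias the mean (the inclusive reading is
available via `include_diagonal=True`).  Group comparisons of tract values
use unpaired Student t-tests (equal variance; Welch behind a flag), starred
at 0.05/0.01/0.001.

Overall-FC is the per-subject mean over all elements of one FCM kind.  The
group trend is normalized by the affine map sending the CN mean to exactly
1 and the ADD mean to exactly 0; the same map rescales all group means and
SDs (SDs by `1/(m_CN - m_ADD)`), and the identical procedure applies to
neuropsychological scores.

## FC-behavior association

Each FCM element is Pearson-correlated with each neuropsychological score
(MMSE, CDR-global, CDR-SOB, GDS, FAQ, WMS-LMII, ADAS-Cog, Hachinski)
across subjects, pairwise-complete over missing scores and with no
imputation; subjects lacking every score are excluded up front.  BH-FDR is
applied per score over that score's full element matrix (not pooled across
scores), and the display copy zeroes non-surviving coefficients; tract
averages are taken over the zeroed copy (the raw matrix remains
available).

The combined-feature analysis trains a random-forest regression of each
score on all WM FC elements after the same cumulative importance-based
feature selection used for classification (regression criterion: OOB MSE
increase).  Fit quality is the Pearson r between true scores and
out-of-fold predictions from 10-fold CV, with `R² = r²` (the
`1 - SSE/SST` definition is available via `r2_mode="score"`).  By default
the selection is repeated inside every fold (`nested=True`): selecting
once on all subjects leaks the evaluation subjects into the selection and
inflates R² substantially at desk-scale cohort sizes — under a permuted
score the nested estimate stays near zero while the leaky variant does
not, which a dedicated test demonstrates.

## Staging classification

Contrasts are CN versus cumulative patient sets in stage order: ADD;
lMCI+ADD; MCI+lMCI+ADD; eMCI+…; SMC+… (contrasts referencing absent groups
are skipped with a warning).

**Feature selection.**  A 200-tree random forest scores every feature by
out-of-bag permutation importance: for each tree, the drop in OOB accuracy
when one feature's OOB values are shuffled, averaged over trees.  (The OOB
sets are reconstructed from each tree's stored bootstrap seed; the
per-tree evaluations are batched for speed.)  Features with non-positive
importance are discarded; the rest are ranked descending (ties keep
original index order) and added five at a time (the final remainder
included), and the cumulative set minimizing 10-fold CV error of the
downstream model is kept, preferring the smaller set on ties.  The curve
is evaluated with a balanced RBF-SVM for classification and a lighter
50-tree forest for regression — the curve only needs to rank set sizes.

**SVM.**  An RBF-kernel SVM is tuned by stratified 10-fold CV error over
`C ∈ {0.1, 1, 10, 100}`, `gamma ∈ {0.1, 1, 10}/d` (d = feature count) and
a misclassification-penalty ratio for the patient class in
`{1, n_ctrl/n_pat, 2·n_ctrl/n_pat}`, compensating group imbalance.  CV
error is the mean 0/1 misclassification rate.  Out-of-fold decision values
at the tuned setting are pooled into a single ROC curve; AUC is the
trapezoidal area, and sensitivity/specificity are read at the
Youden-optimal point (J = sensitivity + specificity - 1), since no
operating-point rule is canonical.  Ties in the hyper-parameter grid
resolve in grid order, making results deterministic for a fixed seed.

`stage_classification(nested=False)` (the default) selects features and
tunes hyper-parameters on the full contrast data before the 10-fold ROC —
the straightforward protocol, whose error estimate is optimistic because
selection sees the evaluation subjects.  `nested=True` repeats selection
and tuning inside each outer fold for an unbiased generalization estimate;
both are exposed and the output records which protocol produced it.

## Synthetic cohort

The generator emulates a six-group elderly cohort (CN, SMC, eMCI, MCI,
lMCI, ADD) at an ADNI-like acquisition: 140 frames at TR = 3 s by default,
30 subjects per group unless configured otherwise.

**Signals.**  Each subject's ROI series is a zero-mean stationary Gaussian
multivariate sequence obtained as `Z L^T` with `L` the Cholesky factor of
the group's target correlation matrix (an optional AR(1) temporal filter
is off by default).  The baseline target is equicorrelation at 0.2 — a
modest level typical of WM-involving resting-state correlations.

**Planted deficits.**  A configured set of WM-involving edges is reduced
by a group-specific delta, graded with stage (defaults 0 / 0.02 / 0.05 /
0.08 / 0.15 / 0.25 from CN to ADD, mirroring deficits that emerge in the
late stages).  When the edge set forms a complete bipartite tract x
partner block — the default: 5 tracts x 20 GM partners = 100 edges — the
deficit is planted through a rank-one contrast (+1 loading on deficit
tracts, -1 on partners): the cross edges drop by exactly delta, every
other WG entry is untouched, and positive semi-definiteness is guaranteed
for `delta ≤ 1 - base` (the side effects are confined to the within-tract
and within-partner blocks).  Arbitrary edge sets fall back to direct entry
subtraction with eigenvalue-clip repair (floor 1e-8, re-normalized
diagonal), refused with a hard error naming the group if the repair moves
any entry by more than 0.05.

**Motion.**  Six-column tables (3 translations in mm, 3 rotations in
radians) follow a slow random walk (steps of 0.01 mm / 0.0002 rad);
spikes occur per frame with probability 0.03 as a persistent 0.8 mm
translation step — chosen translation-only so the FD at the spiked frame
is unambiguous — accompanied by an additive signal artifact (+3 z-units on
every ROI) so that censoring demonstrably matters.

**Scores.**  Each neuropsychological score is an affine function of the
subject's group-level true overall-FC plus Gaussian noise, anchored so the
CN and ADD group means land at clinically typical values (e.g. MMSE
29.1 → 22.4, ADAS-Cog 9.6 → 22.7), with residual SDs at typical
within-group spreads and clipping to each instrument's range (MMSE
[0, 30], CDR-global [0, 3], etc.).  GDS and Hachinski are generated
FC-independent, reflecting instruments that do not track AD-specific
connectivity decline.

**What this does not emulate.**  No hemodynamic response, scanner noise
spectra, spatial smoothness, physiological noise or site effects on the
signals (site is a purely label-level covariate); within a group all
subjects share one target matrix, so between-subject FC variance is purely
sampling variance.  Passing recovery tests therefore shows the estimators
are correct and calibrated under the stated model, not that real ADNI
effect sizes are reproduced — deficit sizes are free simulation
parameters, not estimates.

## Validation studies and problem sizes

The `wmfc.validation` module backs both the acceptance tests and
`scripts/acceptance.py`; sizes were chosen to give stable statistics at
desk scale:

- *Null calibration*: complete-null cohort, 20/group, 120 frames, full
  48 x 82 WG matrix, 2,000 permutations.
- *Deficit recovery*: 10 replicates of 50/group, 200 frames, delta 0.25 on
  the default 100-edge block, 5,000 permutations, FDR 0.05; sensitivity
  and false-discovery proportion are scored against the planted edges,
  tract-wise t-tests against the 5 deficit tracts.
- *Selection recovery*: 10 planted features tagging a latent stage signal
  among 500 noise features, 100 subjects, 5 seeds.
- *Staging*: 5 replicates of a graded cohort (60 CN, 35 per patient group,
  140 frames, 10 WM x 14 GM ROIs, deltas 0.02-0.3); all five cumulative
  contrasts with the full selection + SVM protocol.  On these strongly
  separable cohorts the easy contrasts saturate at AUC 1, so the ordering
  check asserts the AUC never rises and strictly declines overall as
  earlier stages are pooled in.
- *Anchors*: any cohort with CN and ADD present; the normalization is
  exact by construction and checked for exactness.

## Degenerate inputs and edge policies

Empty ROI masks keep their registry slot (matrix shapes never change) and
propagate NaN; all reductions are NaN-aware and pairwise-complete.
Constant columns yield NaN correlations; zero pooled SD yields NaN effect
sizes; a constant score yields NaN associations.  CN and ADD means equal
makes the trend normalization a hard error.  All randomness flows from
explicit seeds (the pipeline expands one master seed per stage), and
identical configurations reproduce byte-identical outputs.

## Known limitations

- The permutation/FDR resolution interaction above means single-element
  effects are undetectable at matrix scale; this matches the method's own
  multiple-comparison behavior.
- The equicorrelation-plus-block-contrast target is the simplest structure
  satisfying the pipeline's assumptions; real FC matrices have richer
  community structure that may affect FDR behavior under dependence.
- The default (non-nested) staging protocol overstates generalization on
  small cohorts; use `nested=True` when an unbiased error estimate is the
  goal.
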