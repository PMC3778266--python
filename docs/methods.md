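# Methods

## The question the pipeline answers

Two widely used morphometry techniques — surface-based cortical thickness
estimation and voxel-based gray-matter volumetry — each produce a ranking of
brain regions by how well they separate diagnostic groups. If a disease
stage has a real, technique-independent anatomical signature, the two
rankings should agree. `roiconcord` operationalizes that check for
amyloid-stratified cohorts: amyloid-negative cognitively normal subjects
(CN−), amyloid-positive normals (CN+, the putative preclinical stage whose
signature is in question), and amyloid-positive MCI/AD patients (a positive
control with a well-established atrophy signature).

The analysis chain is: harmonize each technique's sub-region measurements
onto a common master-ROI set → classify amyloid status from the continuous
PET ratio → propensity-match the CN− comparison group → per-ROI
Mann-Whitney AUROC and rank for each group comparison and technique →
bootstrap CIs for each ROI's rank → Lin's concordance correlation (CCC)
between the two techniques' rank vectors → repeat under cut-point
sensitivity rules.

## Statistical machinery

**AUROC as effect size.** For two groups, AUROC = P(random reference
subject's measure > random affected subject's measure), ties ½, computed
from midranks as U/(n_a·n_b) with U the Mann-Whitney statistic. It is
invariant under monotone rescaling, so thickness (mm) and volume ratios are
directly comparable. Values above 0.5 mean the affected group has smaller
measures (atrophy). P-values use the exact Mann-Whitney null distribution
when the combined sample is ≤ 20 without ties, else the tie-corrected normal
approximation with continuity correction; the switch point is a convention
(both paths are tested against full enumeration). P-values are reported raw
— no multiple-testing correction — because the object of interest is the
ranking, not family-wise significance.

**Rank bootstrap.** Subject rows are resampled with replacement, stratified
within group (an unstratified mode exists), B = 1000 by default; every ROI's
AUROC and midrank is recomputed per replicate and a percentile interval of
the replicate rank distribution is taken. Whole-row resampling preserves the
cross-ROI correlation that rank uncertainty depends on. Bounds are rounded
outward to integer ranks in [1, R] and widened, if needed, to contain the
point-estimate rank (a raw percentile interval on a discrete scale cannot
guarantee containment). These intervals are *conservative*: in calibration
simulations with graded true effects (8 ROIs, n = 100/group, B = 200) the
true rank falls inside the nominal 95% interval ≈ 99.9% of the time. Wide,
honest intervals are the intended reading — a narrow interval is meaningful,
an exact 95% coverage is not claimed.

**Concordance.** Lin's CCC on the paired rank vectors,
`2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with population (n-divisor) moments —
Lin's original estimator; the (n−1) variant is available via `ddof=1` and
differs negligibly at R = 28. CCC ≤ |Pearson r| always, with equality only
when the rankings agree in location and scale; identical rankings give 1,
exact reversal of 1..n gives −1. Midranks (possibly fractional) enter
directly. Per-ROI Spearman correlations between the two techniques' raw
harmonized values, pooled over all analysis subjects, complement the
rank-level CCC (summarized by median and range); per-group correlations are
available from the same function applied to group subsets.

**Harmonization.** Volumes of a master ROI's constituents are summed and
divided by that technique's per-subject total intracranial volume; thickness
constituents are combined by a surface-area-weighted mean over *all*
(sub-ROI, hemisphere) pairs — the single pooled rule reduces to the familiar
left/right formula `(A_L·t_L + A_R·t_R)/(A_L + A_R)` in the two-constituent
case. Thickness is never TIV-adjusted (cortical thickness does not scale
with head size). The packaged 28-ROI map pairs a Desikan-style surface
parcellation (thickness, with hippocampus and amygdala carried as volumes)
with an AAL-style volumetric parcellation, plus an all-volume variant of the
surface scheme for the volume-substitution sensitivity analysis. The map is
a reconstruction from conventional atlas correspondences, not a published
key; it is a plain CSV and fully overridable.

**Cohort selection.** Amyloid positivity: ratio ≥ cut-point (default 1.5).
The boundary case (exactly at the cut-point) classifies positive, and the
sensitivity exclusion band (default 1.3–1.5) is a closed interval — both are
deterministic conventions for boundaries the strict "< cut" / "> cut"
definitions leave open, and both are configurable. Matching: logistic
propensity model of CN+ membership on age, sex and education, then greedy
1:1 nearest-neighbor matching without replacement on the logit of the
propensity score, treated subjects processed hardest-first (descending
propensity); the seed only breaks exact ties, so matching is reproducible.
If the control pool is exhausted (possible under the 1.4 cut-point variant),
all controls are matched and the shortfall is reported. Calipers, optimal
matching and matching with replacement are deliberately out of scope.

**Sensitivity analyses.** Three standard variants rerun classification,
matching and the full comparison set with everything else fixed: cut-point
1.4; cut-point 1.5 with the 1.3–1.5 band excluded; and the surface
technique's volumes substituted for its thicknesses. Matching is re-run
inside each variant because membership changes change the match pool. A
variant whose rule equals the primary rule reproduces the primary outputs
bit-exactly (stage seeds are derived once from the study seed and shared),
which is the pipeline's self-consistency check.

## The synthetic cohort generator

No subject-level data from the motivating study design are public, so the
generator is a documented stand-in that reproduces the *statistical
structure* the analysis assumes, not the source distributions.

Single-factor latent model per subject i, ROI r: latent atrophy
`a_ir = −δ[g,r] + z_ir` (z standard normal; δ ≥ 0 in standardized units, one
row per non-reference group; positive δ lowers the observed measure). Each
observation channel t sees `s_irt = λ_t·a_ir + √(1−λ_t²)·e_irt` with
independent e, so λ_t ∈ [0,1] is the channel's loading on the shared signal
and λ_1·λ_2 is the ceiling on cross-channel correlation. Observed measures
are affine rescalings of s into plausible units; simulated volumes scale
with the subject's simulated TIV so downstream TIV-normalization recovers
the standardized signal exactly. The closed-form group-separation AUROC,
`Φ(λδ/√2)`, is exposed as `true_auroc` and anchors the recovery tests.

Defaults (chosen once, as plausible values for an elderly amyloid-imaging
cohort; they are study conditions, not fitting targets):

- group sizes 215 / 115 / 88 (CN−, CN+, MCI/AD+); λ = 0.7 per channel;
- δ for MCI/AD+: a graded anterior-medial-temporal/parietal signature
  (entorhinal 1.3, hippocampus 1.2, middle/inferior temporal 1.1, inferior
  parietal 1.0, …, sensorimotor/occipital ≤ 0.3); δ for CN+: weak scattered
  effects (≤ 0.2);
- age ≈ N(80, 5–7.5) years, ~45% female, education ≈ N(14.5, 2.5) years,
  per-group means configurable (covariate imbalance is a config knob);
- amyloid ratio: truncated normals — CN− centered 1.25 (sd 0.09, < 1.5) so
  a modest minority of negatives sit in the 1.3–1.5 borderline band; CN+
  centered 1.85, MCI/AD+ 2.10 (> 1.5). The ratio is independent of the
  latent atrophy by default (`pib_atrophy_coupling = 0`), with an optional
  coupling coefficient for power studies;
- TIV ≈ N(1.45·10⁶, 1.3·10⁵) mm³, +12% for males; the second technique's
  TIV is the first times a lognormal factor (σ = 0.045), giving the high
  cross-technique TIV correlation typical of real pipelines;
- sub-ROI disaggregation: volumes split by fixed per-sub-ROI fractions
  (sums reconstruct the master exactly); hemispheric thicknesses get 0.03 mm
  independent jitter and lognormal per-subject surface areas (cv 0.15),
  which attenuates the thickness channel's effective λ by < 1%.

What the generator does **not** emulate: spatial covariance below the ROI
level, bimodal amyloid distributions, measurement-technique biases that
differ *systematically* by region, longitudinal structure, and missing data.
Consequently, passing tests demonstrate that the statistical machinery is
correct and calibrated under the assumed structure — not that any particular
real cohort has (or lacks) a preclinical atrophy signature.

## Numerical choices and degenerate inputs

- Same seed + same config ⇒ bit-identical cohorts, matches, bootstrap CIs
  and output CSVs. Stage seeds derive from one top-level seed via
  `SeedSequence`; per-table bootstrap seeds mix in a CRC of the
  comparison/technique label so tables are independent but reproducible.
- Ties: midranks everywhere (AUROC, ROI ranks, within bootstrap replicates).
- Degenerate groups inside a bootstrap replicate are kept (midranks absorb
  them); empty groups, zero total surface area, nonpositive TIV or ratios,
  constant-and-equal CCC inputs, and mismatched ROI sets raise typed errors
  naming the offending entity. A constant column makes that ROI's Spearman
  undefined: reported as NaN, excluded from the summary, with a warning.
- Logistic propensity fits fall back to an L2-penalized fit (with a warning)
  when the MLE does not exist (perfect separation).

## Problem sizes used in the shipped checks

The test-suite and `scripts/acceptance.py` simulations use: the default
study scale (418 subjects, B = 1000, all variants) for the end-to-end run;
n = 2000/group for closed-form AUROC recovery; 10,000 null datasets
(n = 30/30) for type-I calibration; 200 datasets × B = 200 for rank-CI
coverage; and 50 replicate cohorts for the concordance contrast. These sizes
put Monte-Carlo error comfortably below the assertion tolerances while
keeping a full run in the low minutes on one CPU.

## Known limitations

- The packaged ROI map is a reconstruction; analyses of real exports should
  supply the project's own map CSV.
- Bootstrap rank CIs are conservative (see above); they should be read as
  "at least 95%" intervals.
- CCC is computed on point-estimate ranks only; no CI is attached to the
  CCC itself (a bootstrap CCC interval would require nesting and is
  deliberately omitted).
- Greedy nearest-neighbor matching is not globally optimal; with heavy
  overlap it is near-optimal, and the algorithm, distance and order are
  fully specified for reproducibility.
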