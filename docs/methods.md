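# Methods

This note records the statistical model behind the package, the defaults
and why they were chosen, and the numerical conventions that resolve the
places where the procedure is genuinely underdetermined.

## The screening problem

The instrument diagnoses a distal symmetric polyneuropathy from four
bilateral items: feet pain (numeric rating 0–10), feet numbness (0–10),
timed great-toe vibration sense (seconds; *shorter* perception is
abnormal), and the ankle reflex (ordinal grade 0 normal / 1 hypoactive /
2 absent).  Each item is dichotomised per side against its cutoff
(defaults: pain ≥ 5.5, numbness ≥ 2.55, vibration ≤ 13.2 s, reflex grade
∈ {1, 2}), tallied as the count of abnormal sides, and combined with the
rule *(bilateral pain OR reduced vibration) AND (bilateral numbness OR
reduced reflex)*.  Comparisons are inclusive on the abnormal side, and the
direction of abnormality is stored per measurand rather than hard-coded.

The printed 21-row positivity rubric is a strict subset of this verbal
rule: the four quadruples with bilateral pain and bilaterally reduced
reflex but neither bilateral numbness nor reduced vibration — (2,0,0,2),
(2,1,0,2), (2,0,1,2), (2,1,1,2) — satisfy the verbal rule but do not
appear in the printed table.  The package treats the verbal rule as
canonical (it is the stated case definition), offers the strict rubric as
`table2_strict`, and logs the discrepancy whenever the rubric is
enumerated; whether the missing rows are intentional is not guessed.

## Synthetic cohort model

A single latent severity `S` per patient drives every measurement:
`S ~ N(0, 1)` in the neuropathy-free class and `N(Δ, 1)` in the neuropathy
class, with class membership drawn at the configured prevalence (default
28/66 ≈ 0.424, the development-cohort rate).  A shared latent is the
simplest structure consistent with a multi-item scale measuring one
construct; per-item noise controls how much the items decouple.

Each side measurement of item *j* is
`X = a_j ± b_j (S + σ_j ε)`, with the sign set by the item's orientation,
`b_j` a fixed scale (measurement units per severity unit) and `σ_j` the
side-level noise.  Given severity, the two sides are independent.

**Calibration.**  The generator solves, per item, for the location and the
side-noise so that the *bilateral* abnormality indicator (both sides past
the cutoff) hits a target (sensitivity, specificity) against latent class:
with `p(s) = Φ((s − u)/σ)` the single-side abnormality probability,

    E[p(S)² | case] = sensitivity,   E[p(S)² | control] = 1 − specificity,

two equations in `(u, σ)` solved by Gauss–Hermite quadrature (80 nodes)
and a hybrid Newton root finder, then `a_j = cut − (±) b_j u`.  Defaults
target the development-cohort item accuracies: pain (0.74, 0.81),
numbness (0.778, 0.632), vibration (0.74, 0.81), reflex (0.857, 0.684).
Monte-Carlo checks at n = 5000 confirm the dichotomised items reproduce
the targets within ±0.03.  If an `item_noise` entry is supplied the noise
is taken as given and only the location is solved (to match specificity).

**Defaults and units.**

| parameter | default | rationale |
|---|---|---|
| severity shift Δ | 2.0 SD | a large clinical separation; must exceed the binormal d′ implied by each item's targets for the calibration to be solvable |
| item scales b (pain, numb, vib, reflex) | 2.0, 0.75, 3.0 s, 1.0 | clinically plausible spreads on each native scale, and small enough that the consensus-cutoff estimator is approximately unbiased for the generating threshold |
| QST abnormality prob. (case/control, per parameter) | 0.35 / 0.05 | gives ≈99% / ≈14% probability of ≥2 abnormal of 13 |
| IENFD log-normal (case/control) | ln-mean 1.70 / 2.35, ln-sd 0.40 / 0.35 | ≈80% of cases and ≈18% of controls at or below 7.63 fibers/mm |
| clinical signs prob. (case/control) | 0.85 / 0.12 | a sensitive but imperfect structured examination |
| examination score per side | round(1.0 + 2.5·S + N(0, 0.8)), clipped 0–21 | puts most cases above the symmetric total cutoff of 8 |
| bilateral feet pain prob. (case/control) | 0.70 / 0.08 | matches the ≈69% body-map rate among screen positives |
| interview-item probs (cases) | (.44, .11, .56, .33, .44, .56, .22) | the symptom frequencies observed in the internal-validation cohort |
| rater-2 error | flip 0.02; additive sd 0.3/0.3/0.5 | keeps per-item inter-tester Spearman ρ ≥ 0.93 |

Pain/numbness values are kept continuous and clipped to [0, 10] (integer
rounding would shift the numbness dichotomy at 2.55); vibration is clipped
at 0; clipping never moves a value across its cutoff, so calibration is
unaffected.  The reflex is generated by double-thresholding a latent
per-side variable (hypoactive at the calibrated threshold, absent one
scale unit above); no continuous reflex scale is reconstructed.

`reliability_config()` is a separate preset (Δ = 2.5, common item noise
0.85, prevalence 0.433) calibrated once, in the large-sample limit, so
that the four bilateral indicators have the inter-item correlation implied
by the published internal consistency: it yields Cronbach's α → 0.880 and
a mean corrected item-total correlation → 0.740 at n = 20 000.

**What the generator does not emulate:** demographic structure, treatment
exposure, missing data, item-specific causes of false positives (all
cross-item dependence flows through the single latent), and any
non-Gaussian severity distribution.  Passing tests therefore show that the
*analysis machinery* is correct and well-calibrated, not that the
instrument performs identically on real patients.

## Cutoff selection

All cutoff curves are step functions of the cutoff, evaluated at every
unique observed value (plus a virtual all-negative cutoff beyond the
extreme).  For root finding the difference curve is treated as
piecewise-linear between adjacent candidates; an exact-zero run, which on
a step curve corresponds to a half-open cutoff interval, resolves to the
interval midpoint.  Ties in the minimum-cost criterion resolve to the
candidate nearest the sensitivity/specificity crossover.

- **Sensitivity/specificity crossover** — where the two curves cross.
- **Predictive-value crossover** — where PPV and NPV cross.  PPV − NPV
  also vanishes on the uninformative locus sens + spec = 1, so the search
  is restricted to cutoffs with a positive Youden index, where the
  crossing is unique.
- **Likelihood-ratio crossover** — LR+ ≥ 1 ≥ LR− wherever a test is
  informative, so the two curves never literally intersect.  The package
  crosses log LR+ with −log LR− (equivalently LR+·LR− = 1), again
  restricted to positive-Youden cutoffs; there the crossing is unique and
  coincides analytically with the sensitivity = specificity point.  A
  perfectly separating cutoff (LR+ = ∞, LR− = 0 simultaneously) is
  treated as a touching point.
- **Minimum misdiagnosis cost** — cost(c) = (c_fp·FP + c_fn·FN) /
  (c_fp·N⁻ + c_fn·N⁺), normalised to [0, 1] with 0 meaning perfect
  classification; default weights 1:2 (FP:FN ratio 0.5).  The unit costs
  printed for correct classifications are carried in `CostWeights` but do
  not enter this normalised form, and the absolute cost values printed for
  the original cohort are not reproducible without the raw data.

The consensus cutoff is the geometric mean of the four criteria.  It
requires a positive scale; scales containing zero use a documented +1
offset, applied before and removed after averaging.  On coarse ordinal
grids (the reflex tally) a criterion's curves may genuinely never cross;
the cohort-level report then flags that item's cutoffs as NaN instead of
failing.

Partial eta-squared is SS_effect/(SS_effect + SS_error) from an ordinary
linear-model decomposition (type-II sums of squares via statsmodels),
equal to classical eta-squared when no covariates are given.  The default
is factor-only, since the covariate set used in the original ANCOVA is
unstated.

## Validation statistics

Likelihood ratios use the standard definitions with no continuity
correction; a perfect specificity reports LR+ = +∞ and perfect
sensitivity reports LR− = 0, matching the published treatment.  Post-test
probability is exact odds arithmetic; note the published field-test values
(LR 5.29, post-test 92%) were read off a nomogram graphic — exact
arithmetic on the same 2×2 table gives 5.21 and 91%, and the package
computes exactly and logs the comparison.  Zero-denominator metrics raise
named errors rather than returning silent zeros.

Item-total correlations are *corrected* (item vs total-minus-item) Spearman
correlations with midranks; the uncorrected variant is available but
inflates each item's correlation with its own contribution.  Cronbach's
alpha uses sample variances (n − 1).  The content validity ratio follows
the Lawshe form (n_e − N/2)/(N/2).

Reference standards: quantitative-sensory-testing abnormality defaults to
|z| > 1.96 (a two-sided normative band; the original criterion says only
"abnormal", so the threshold is configurable); the fiber-density boundary
is inclusive (≤ 7.63).  The examination-score proxy excludes — rather than
classifies — records whose smaller side carries less than 25% of a
supra-threshold total; the asymmetry fraction is a declared stand-in for
the stated intent ("exclude high unilateral scores") and is configurable.

## Rule search

"All possible cutoff combinations" is operationalised as every
non-constant *monotone* Boolean function of the four bilateral indicators
(166 of them; monotone because abnormal findings can only add evidence of
neuropathy), enumerated by brute force over all 2¹⁶ truth tables and
ranked by Youden index with a deterministic lexicographic tie-break.

## Problem sizes used in tests

Monte-Carlo calibration checks use one 5000-patient cohort; parameter
recovery uses five seeds at n = 5000; the rule-search operating-point
check uses five seeds at n = 500 (the scale of the original in-silico
test) and compares the 5-seed mean; reliability uses the n = 30 pilot
size for alpha and n = 1000 for inter-tester concordance.  Exact-oracle
comparisons (pair-counting AUC, midrank Spearman) run at n ≤ 200 where
brute force is cheap.  Seeds 0–4 are fixed throughout.

## Known limitations

- All inter-item dependence flows through one latent severity; real items
  share method-specific error the model cannot express.  This is visible
  in the rule search: with the published per-item specificities, any model
  with class-conditionally independent (or positively dependent) item
  errors caps the combination rule's specificity near 0.80–0.82, short of
  the 0.90 reported on the original data.
- The printed per-measurand AUCs are not recoverable from the printed
  cutoff operating points under an equal-variance Gaussian latent (the
  operating point (0.74, 0.81) forces AUC ≈ 0.86); synthetic AUCs are
  validated against independent pair-counting oracles instead of printed
  values.
- Confidence intervals for the accuracy metrics and formal ROC-comparison
  tests are out of scope.
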