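# chant

A development-and-validation toolkit for **CHANT**, a 4-item bedside screen
for HIV-associated sensory neuropathy (HIV-SN), and for the neuropathic-pain
triage that follows a positive screen.

HIV-SN is a length-dependent distal symmetric polyneuropathy affecting a
large fraction of people on antiretroviral therapy.  Definitive diagnosis
needs quantitative sensory testing and skin biopsy, which are unavailable in
most clinics.  CHANT instead scores four quick bilateral items on the feet —
pain and numbness (symptoms), timed great-toe vibration sense and the ankle
reflex (signs) — each tallied as the number of abnormal sides (0/1/2), and
calls neuropathy when

```
(bilateral feet pain  OR  bilaterally reduced vibration)
AND (bilateral feet numbness  OR  bilaterally reduced ankle reflex)
```

This package implements, as tested reusable code, the full analysis needed
to build and validate such an instrument:

- **`chant.synthetic`** — seeded synthetic cohorts driven by a single latent
  severity, with each item's bilateral sensitivity/specificity calibrated to
  configurable targets; second-rater replicates and expert-panel ratings.
- **`chant.reference`** — the composite 2-of-3 reference standard (clinical
  signs, ≥2 of 13 abnormal QST z-scores, intraepidermal nerve fiber density
  ≤ 7.63 fibers/mm) and the examination-score proxy (total cutoff 8 applied
  symmetrically, high unilateral scores excluded).
- **`chant.measurand`** — orientation-aware empirical ROC/AUC, partial
  eta-squared, four cutoff-selection criteria (sensitivity/specificity
  crossover, predictive-value crossover, likelihood-ratio crossover,
  minimum weighted misdiagnosis cost with FP:FN = 1:2) and their
  geometric-mean consensus.
- **`chant.scorer`** — item scoring, the combination rule (verbal form and
  the strict 21-row printed rubric, whose 4-quadruple discrepancy is
  surfaced), and an exhaustive in-silico search over all 166 non-constant
  monotone Boolean combination rules ranked by Youden index.
- **`chant.triage`** — 7-item pain-interview score (positive at ≥3/7), body
  map bilateral-feet-pain detection, and the five-way classification
  (neuropathic pain / POPNO / neuropathy without foot pain / follow-up /
  no neuropathy).
- **`chant.validation`** — 2×2 accuracy metrics with likelihood ratios,
  exact pre-/post-test probability (Fagan) arithmetic, Cronbach's alpha,
  corrected item-total and inter-tester Spearman correlations, and the
  content validity ratio CVR = (n_e − N/2)/(N/2).
- **`chant.pipeline` / `chant.cli`** — a deterministic end-to-end pipeline
  (`simulate → develop → score → triage → validate → report`) and a `chant`
  command-line tool.

## Worked example

The internal-validation cohort gives the 2×2 table TP=10, FP=3, FN=0, TN=17
against the examination-score reference:

```bash
$ chant validate --table 10 3 0 17 --pretest 0.43
sens 100%  spec 85%  PPV 77%  NPV 100%  LR+ 6.67  LR- 0.0
pre-test 43% -> post-test 83%
```

Every reference-positive patient was caught (sensitivity 100%, NPV 100%,
LR− 0); three false alarms give specificity 85% and PPV 77%.  A positive
likelihood ratio of 6.67 lifts a 43% pre-test probability of neuropathy to
83% post-test (post-odds = pre-odds × LR+).

A full synthetic run:

```bash
chant report --outdir out/          # all six artifacts + manifest
chant simulate --n 500 --seed 0 --output cohort.csv
chant score --input cohort.csv --rule verbal --output scores.csv
```

`out/summary.md` contains the per-measurand development table (AUC,
crossover sensitivity/specificity, partial eta-squared, the four cutoffs
and their geometric mean, minimum misdiagnosis cost), the validation
metrics, reliability coefficients and the triage roll-up.

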