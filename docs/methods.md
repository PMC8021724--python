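# Methods

## The score

The SIMPLE score sums 14 items, each 0–3 points, at scheduled postnatal
hours (6, 12, 18, 24, 48, 72 h of life). Five items are static (maternal
chorioamnionitis, completed antenatal steroid course, birth weight, cord
blood-gas base deficit, FiO₂ at NICU admission) and contribute identically
at every hour; the remainder describe the infant's state during the
evaluation episode (hypotension requiring inotropes, tachycardia, invasive
ventilation mode, metabolic and respiratory acidosis, maximum PIP, PIP and
FiO₂ reduction relative to the prior assessment, cumulative surfactant
doses). The per-item maxima are (1, 1, 3, 2, 1, 2, 3, 3, 3, 2, 2, 2, 2, 2),
so the attainable total is an integer in [0, 29]; a dynamic-programming
enumeration over the items' attainable point sets shows every integer in
that range is reachable (the invasive-ventilation item contributes only
{0, 1, 3}: no conventional mode scores 2).

### Conventions the rubric itself leaves open

These choices are applied uniformly and unit-tested:

- **Base deficit as magnitude.** All base-deficit inputs (cord and episode
  gases) are stored as non-negative magnitudes — a base excess of −14 mmol/L
  is entered as 14. Only this reading makes the printed bins monotone in
  severity.
- **Shared bin endpoints go to the lower-severity bin.** Birth weight
  1000 g scores 1 (not 2); pH 7.25 scores 1 (not 2); an episode base deficit
  of exactly 10 scores 1; PCO₂ of exactly 45 (and 55, 65) scores the lower
  bin. Outer bins printed as strict inequalities stay strict (heart rate 160
  and 180 both fall in the middle bin because "<160" and ">180" are strict).
- **Hypocapnia.** PCO₂ below 35 mmHg falls outside every printed bin and
  scores 0: low PCO₂ is not respiratory acidosis.
- **Metabolic acidosis** takes the worse of the pH ladder and the
  base-deficit ladder, per the rubric's footnote.
- **Inapplicable items score 0 and are flagged.** An infant who is not
  invasively ventilated scores 0 on maximum PIP and PIP reduction. An infant
  on room air (FiO₂ = 21%) scores 0 on FiO₂ reduction — treating the
  "<10% reduction" bin literally would hand every well infant 2 permanent
  points, which is inconsistent with the score's own control-group
  distributions (a healthy ELBW control would otherwise be unable to score
  below ~5, while the observed control medians sit at 4 with minima of 2,
  exactly the birth-weight floor).
- **Prior assessment at 6 h.** The admission FiO₂ recorded for every infant
  serves as the "prior" for the 6 h FiO₂-reduction item. No admission PIP is
  part of the infant record; if one is known it can be passed to
  `score_trajectory(..., admission_pip=...)`, otherwise the 6 h PIP-reduction
  item is scored 0 with a `pip_reduction:no_prior` flag.
- **Missing dynamic values** are carried forward from the most recent
  earlier assessment and flagged `…:carried_forward`; a value never observed
  scores 0 with a `…:missing` flag. Reported totals therefore remain defined
  for every infant, and every imputation is visible in the output.

Because totals are integers, the decision rules "score > 8.5" and
"score > 8" classify identically; the published cut-offs use both forms.

## Echo criterion

Hemodynamic significance at an echo screen (24, 48 or 72 h): duct inner
diameter indexed to current weight > 1.5 mm/kg **and/or** LA/Ao > 1.5, both
strict. The infant-level echo label is positive if any screen is positive
(any-hour rule; the first positive hour is reported as the deciding hour).
The cohort's *case* label additionally requires clinical symptoms
(`symptomatic` flag), because early control indices can legitimately exceed
1.5: the criterion alone does not separate the groups on day 1.

## Synthetic cohort generator

No patient-level data are distributed, so a generator emulates the study
conditions: 48 infants, 30 cases / 18 controls, with

- group-conditional item prevalences fixed at the published per-group counts
  (cases vs controls): chorioamnionitis 21/30 vs 5/18, missing steroid
  course 19/30 vs 4/18, hypotension on inotropes 22/30 vs 2/18, tachycardia
  16/30 vs 3/18, HFOV 9/30 vs 1/18, repeat surfactant 9/30 vs 0/18;
- birth weight and gestational age drawn from truncated normals matched to
  the published medians and ranges (cases 720 g (340–990), controls
  770 g (620–995), 25 vs 26 weeks);
- continuous physiology (FiO₂, PIP, PCO₂, pH, base deficit, heart rate) from
  truncated normals with per-hour profiles: cases wean FiO₂/PIP modestly
  after surfactant, deteriorate into 48 h (ductal steal) and improve
  slightly by 72 h; controls wean steadily to room air and extubate after
  24 h. Control ventilation is set to 5/18 — the corresponding published
  count row mixes denominators, and a higher rate is arithmetically
  incompatible with the published control score medians;
- echo indices from truncated normals matched to the published per-day
  medians and ranges; each case is forced to cross the hsPDA threshold at a
  deciding hour drawn 13/14/3 (of 30) for 24/48/72 h, mirroring when closure
  treatment began; controls are drawn from their printed ranges unmodified;
- optional outcome flags (mortality 16/30 vs 0/18, severe IVH 15/30 vs 1/18)
  for demonstration summaries only.

**Totals are never sampled.** The generator draws item-level data only,
recomputes every per-hour total through the scoring engine, and
rejection-samples each infant's trajectory until all six totals lie inside
the published per-group (min, max) envelope for that hour (case envelopes
12 (5–19) … 15 (10–23) … ; control envelopes 4 (2–18) … 4 (2–12)). This keeps
the generator an honest exercise of the scoring engine rather than a
circular fixture. The distributional parameters were calibrated once so the
per-group per-hour *median* totals land on the published medians; with the
defaults the acceptance rate is ≈0.95 and, over 200 replicate cohorts, every
group × hour mean-of-medians sits within ±0.7 points of its target
(tested at ±1).

A feasibility pre-check (`calibrate_items`) bounds the attainable totals
under a plan before sampling and rejects contradictory configurations —
e.g. forcing every control onto HFOV makes the minimum attainable total
exceed the control median target. A global acceptance-rate floor of 10⁻³
guards against silently unreachable envelopes.

Randomness: a single integer seed; each infant receives an independent
substream keyed by (seed, CRC-32 of infant id), so cohorts are reproducible
under reordering and identical seeds yield byte-identical tables.

**What the generator does not emulate:** within-infant autocorrelation
beyond the monotone weaning/deterioration profiles, physiologic coupling
between items (beyond concentrating perinatal risk flags in the ventilated
control subgroup), treatment feedback (surfactant improving gases, closure
treatment altering later scores), or inter-hour echo dynamics. Passing tests
therefore demonstrate correctness of the scoring/evaluation machinery under
the published summary structure, not clinical realism of individual
trajectories.

## Diagnostic evaluation

- **ROC construction:** candidate thresholds are the midpoints between
  consecutive distinct observed scores plus ∓∞ sentinels; the decision rule
  is "score > threshold ⇒ case". The AUC is the trapezoidal area of the
  resulting curve and equals the normalised Mann–Whitney pair statistic with
  ties counted ½ — an exact identity under this construction, tested
  exhaustively on small instances. Ties matter because integer scores tie
  often at n = 48.
- **Optimal cut-off:** Youden's J = sensitivity + specificity − 1, ties
  broken toward the higher threshold (higher specificity); with all scores
  equal J ≡ 0 and the +∞ sentinel is returned.
- **Sensitivity/specificity intervals:** exact two-sided Clopper–Pearson
  from beta quantiles. The published intervals (e.g. 30/30 → 88.4–100.0,
  17/18 → 72.7–99.9) are reproduced to the printed decimal — the strongest
  internal evidence that this was the original tool's method.
- **AUC inference:** DeLong structural components via midranks; the
  single-AUC p-value tests H₀: AUC = 0.5 with the estimated variance, and
  the paired comparison uses the components' covariance. With perfect
  separation the variance degenerates to 0 and the p-value is reported as 0.
  The implementation is cross-checked against a label-permutation oracle, a
  10⁴-resample bootstrap, and R's pROC.

## Group comparisons

Continuous variables: median (range) per group, Mann–Whitney U; the p-value
is exact (full enumeration of group assignments, tie-safe, two-sided by the
|U − mean| tail rule) whenever C(n, n₁) ≤ 10⁴, otherwise a tie-corrected
normal approximation; the method used is reported. Categorical variables:
n (%) per group; Fisher's exact test (two-sided by the probability-mass
rule) when any expected cell is below 5, Pearson chi-square without
continuity correction otherwise. The Fisher/chi-square machinery is scipy's;
the Mann–Whitney exact path is implemented here because the library exact
mode declines ties, and is verified against full enumeration.

## Problem sizes and numerical notes

The test suite and the acceptance script regenerate cohorts at the study's
own size (48 infants); replicate counts are 100–200 cohorts for calibration
checks and 10⁴ resamples/permutations for the Monte-Carlo oracles — sizes at
which every check completes in seconds while Monte-Carlo error stays an
order of magnitude below the tested tolerances. Truncated-normal draws use
rejection with a clipped fallback after 200 attempts; probabilities are
compared with absolute tolerances ~10⁻⁹ where floating-point ties could
otherwise flip a bin.

## Limitations

The package evaluates the score against labels on synthetic cohorts shaped
by published summary tables; it cannot validate the score's clinical
performance, and AUCs on synthetic cohorts (~0.92–0.99 depending on hour and
seed) should be read as consequences of the calibrated group separation, not
as new evidence. The chorioamnionitis definition is consumed as a boolean
input; the underlying five clinical criteria are not re-derived. No
treatment logic (ibuprofen/paracetamol/ligation) is modelled.
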