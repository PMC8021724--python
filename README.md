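# simplepda

A tested Python implementation of the **SIMPLE score** (Scoring preterm
Infants for PDA cLinically without Echocardiographic evaluation): a 14-item
bedside rubric for the early prediction of hemodynamically significant patent
ductus arteriosus (hsPDA) in extremely-low-birth-weight (ELBW) infants,
together with the echo-based hsPDA criterion, a calibrated synthetic cohort
generator, and the full diagnostic-evaluation layer (ROC/AUC, Youden
cut-offs, exact binomial confidence intervals, DeLong comparisons, two-group
summary statistics).

## Who this is for

Neonatology and biostatistics groups who want to apply, audit, or stress-test
a clinical early-warning score for ductal shunting without relying on serial
echocardiography. The package turns the published rubric into executable,
unit-tested code; because no patient-level data are distributed, a synthetic
cohort generator reproduces the statistical structure of the original 48-infant
study population (30 hsPDA cases, 18 controls) so every downstream stage can
be exercised end to end.

## The score

Fourteen items, each worth 0–3 points, summed per assessment hour
(postnatal 6, 12, 18, 24, 48 and 72 h); the maximum total is 29.

| item | 0 | 1 | 2 | 3 |
|---|---|---|---|---|
| maternal chorioamnionitis | no | yes | | |
| completed antenatal steroids | yes | no | | |
| birth weight (g) | >1250 | 1000–1250 | 750–<1000 | <750 |
| cord base deficit (mmol/L) | <12 | 12–16 | >16 | |
| hypotension on inotropes | no | yes | | |
| heart rate (bpm) | <160 | 160–180 | >180 | |
| invasive ventilation | no | conventional | — | HFOV |
| metabolic acidosis (pH / BD, worse of the two) | >7.35 / <4 | 7.25–7.35 / 4–10 | 7.10–<7.25 / >10–16 | <7.10 / >16 |
| respiratory acidosis (PCO₂, mmHg) | ≤45 | >45–55 | >55–65 | >65 |
| maximum PIP (cmH₂O) | <18 | 18–23 | >23 | |
| PIP reduction vs prior | >20% | 10–20% | <10% | |
| FiO₂ at admission (%) | <40 | 40–60 | >60 | |
| FiO₂ reduction vs prior | >20% | 10–20% | <10% | |
| surfactant doses | 0 | 1 | >1 | |

Base deficits are handled as non-negative magnitudes; shared bin endpoints
resolve to the lower-severity bin; an infant with no supplemental oxygen
(FiO₂ = 21%) or no invasive ventilation scores 0 on the inapplicable items,
flagged in the output. See `docs/methods.md` for all conventions.

An infant is labelled **hsPDA by echo** when duct diameter / weight
> 1.5 mm/kg and/or LA/Ao > 1.5 at any of the 24/48/72 h screens; the study
group label additionally requires clinical symptoms.

## Worked example

```python
from simplepda import InfantRecord, TimepointObservation, VentMode, score_trajectory

rec = InfantRecord(
    infant_id="P01", gestational_age=25.0, birth_weight=720,
    chorioamnionitis=True, antenatal_steroid_complete=False,
    cord_base_deficit=8.0, fio2_admission=55.0,
)
obs = [
    TimepointObservation("P01", 6, heart_rate=168, hypotension_inotropes=False,
                         vent_mode=VentMode.CONVENTIONAL, pip=21, fio2=48,
                         ph=7.31, base_deficit=6.0, pco2=52, surfactant_doses=1),
    TimepointObservation("P01", 12, heart_rate=175, hypotension_inotropes=True,
                         vent_mode=VentMode.CONVENTIONAL, pip=21, fio2=50,
                         ph=7.27, base_deficit=7.0, pco2=56, surfactant_doses=2),
]
for bd in score_trajectory(rec, obs):
    print(f"hour {bd.hour:>2}: total {bd.total}")
```

prints

```
hour  6: total 13
hour 12: total 19
```

At 6 h this 720 g infant with chorioamnionitis and no completed steroid
course already scores 13 (birth weight contributes 3, admission FiO₂ and the
ventilated state 1 each, mild mixed acidosis 2); by 12 h new hypotension on
inotropes, a second surfactant dose, rising PCO₂ and static ventilator
settings (a <10% reduction scores 2 on both reduction items) lift the total
to 19 — far above the published decision thresholds (>8.5 at 6 h, >8 at
12–24 h, >6 at 48–72 h).

The same computation runs from the shell over CSV tables:

```bash
simple-pda simulate --seed 1 --out cohort/          # synthetic study tables
simple-pda score --infants cohort/infants.csv \
                 --observations cohort/observations.csv --out cohort/scores.csv
simple-pda evaluate --scores cohort/scores.csv --labels cohort/labels.csv --out eval/
simple-pda compare --cohort cohort/ --out group_summary.csv
simple-pda pipeline --seed 1 --out demo/            # all of the above + report
```

`demo/report.txt` reproduces the shape of the study's score-distribution and
ROC tables on the synthetic cohort: per-hour medians (ranges) by group,
AUCs, Youden-optimal cut-offs, and sensitivity/specificity with exact 95%
Clopper–Pearson intervals.

## Layout

- `src/simplepda/scoring.py` — the 14 item scorers, per-hour assembly, trajectory API
- `src/simplepda/echo.py` — echo indices and the hsPDA criterion
- `src/simplepda/cohort.py` — calibrated synthetic cohort generator
- `src/simplepda/diagnostics.py` — ROC, AUC, Youden, Clopper–Pearson, DeLong
- `src/simplepda/compare.py` — Mann–Whitney, Fisher, chi-square, group tables
- `src/simplepda/io.py`, `pipeline.py`, `cli.py` — validated CSV I/O, end-to-end pipeline, CLI
- `docs/methods.md` — modelling conventions, generator design, limitations
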