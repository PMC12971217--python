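# nasodx

Rule-based diagnosis of nasal obstruction from structured nasoendoscopic
grading, together with the full evaluation stack needed to study how
well such a system performs: multi-rater consensus, diagnostic accuracy
with confidence intervals, paired method comparison, inter-rater
agreement and power analysis.

## The problem

Nasal obstruction has overlapping structural and inflammatory causes —
allergic rhinitis (AR), chronic rhinosinusitis with and without nasal
polyps (CRSwNP / CRSsNP) and deviated nasal septum (DNS) — and a
definitive diagnosis normally needs a specialist with endoscopy, allergy
testing and CT. `nasodx` encodes ENT decision-making over four
validated endoscopic grading scales, recorded for each nostril before
and after a decongestant spray:

| scale | meaning | domain |
|---|---|---|
| INV | internal nasal valve, by middle-turbinate visibility | 0, ⅓ ("maybe 0"), ⅔ ("maybe 1"), 1, 2 |
| IT | inferior turbinate, quartile of airway occupied | 1–4 |
| DNS | septal deviation, fraction of cavity covered | 0–3 |
| Polyp | polyposis extent | 0–4 |

A structure a rater could not see is recorded as `NV` (not visualized),
which is distinct from grade 0.

## The rule engine

Five boolean questions are asked of a resolved exam:

- **Q1** polyp grade ≥ 1 on *both* sides (bilateral polyposis);
- **Q2** IT size reduction (pre − post)/pre ≥ 35% on *both* sides
  (reversible, allergic congestion);
- **Q3** |DNS_L − DNS_R| ≥ 1 post-decongestant (septal asymmetry with
  the nasal cycle cancelled);
- **Q4 / Q5** INV ≥ 1 on *both* sides pre / post decongestant
  (persistent valve obstruction; ⅓ and ⅔ count as below 1).

The resulting vector is looked up in an exhaustive 32-row decision
table mapping to subsets of {AR, CRSsNP, CRSwNP, DNS}; the empty set is
a control. The table is equivalent to the closed form

    CRSwNP ⇔ Q1      DNS ⇔ Q3      AR ⇔ Q2 ∧ Q4
    CRSsNP ⇔ ¬Q1 ∧ Q4 ∧ (¬Q2 ∨ Q5)

but the implementation uses the verbatim, checksum-verified table; the
closed form serves as a test oracle.

Around the engine sit: consensus aggregation of rater panels
(mode → mean on ties → predefined default when all raters say `NV`),
the ≥2-rater vote for visual diagnoses, one-vs-rest
sensitivity/specificity with Wilson (or Clopper–Pearson) intervals,
discordant-pair conditional logistic regression
(log OR = ln n₁₀/n₀₁, SE = √(1/n₁₀ + 1/n₀₁)), Krippendorff's α with a
unit bootstrap, power formulas for two-proportion designs
(n/group = ((z₁₋α/₂ + z_power)/h)²), and a synthetic cohort generator
with known gold labels.

## Worked example

```python
from nasodx import ExamGrading, SideGrades, diagnose, evaluate_questions

exam = ExamGrading(
    participant_id="demo-1", rater_id="consultant-1",
    pre_left=SideGrades(inv=1.0, it=4.0, dns=0.0, polyp=0.0),
    pre_right=SideGrades(inv=2.0, it=3.0, dns=0.0, polyp=0.0),
    post_left=SideGrades(inv=0.0, it=2.0, dns=0.0, polyp=0.0),
    post_right=SideGrades(inv=2/3, it=1.0, dns=0.0, polyp=0.0),
)
print(tuple(evaluate_questions(exam)))   # (False, True, False, True, False)
print(diagnose(exam))                    # frozenset({'AR'})
```

Both turbinates shrank by ≥ 35% (Q2) and the valve was obstructed on
both sides before decongestion but not after (Q4 without Q5): the table
reads this as allergic rhinitis. More narrative walkthroughs live in
`examples/` (single-exam diagnosis, simulate-and-evaluate, inter-rater
agreement, power analysis); each prints the numbers it computes and a
line on what they mean.

## Command line

```sh
nasodx simulate --n 71 --raters 4 --seed 1 --out-dir scratch/run
nasodx diagnose scratch/run/gradings.csv --out scratch/run/diagnoses.csv
nasodx evaluate scratch/run/diagnoses.csv scratch/run/diagnoses.csv \
       scratch/run/gold.csv --out scratch/run/report.json
nasodx agreement scratch/run/gradings.csv --out scratch/run/agreement.json
nasodx power --n 71
```

Grading CSVs are long-format (participant, rater, timepoint, side, four
grade columns, `NV` for not-visualized); diagnosis CSVs use
"+"-joined labels with an empty field for controls. Every output gets a
manifest (config hash, seed, version).

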