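# Methods

## Model and assumptions

`nasodx` implements a deterministic decision-table classifier over
structured endoscopic findings. The unit of input is one participant's
exam: four ordinal grades (INV, IT, DNS, polyp) per nostril per
timepoint (before and ten minutes after a topical decongestant), so 16
grade slots in total. Five boolean questions summarize the exam and an
exhaustive 32-row table maps the question vector to a subset of
{AR, CRSsNP, CRSwNP, DNS}, the empty set meaning "control". The model
assumes:

- the grading scales are closed enumerations (INV additionally carries
  the certainty values ⅓ and ⅔ between grades 0 and 1);
- sides are exactly {L, R} and timepoints exactly {pre, post};
- bilateral findings drive diagnosis — unilateral polypoid masses are
  outside the model (they may be neoplastic and need imaging or
  histology) and produce a logged exclusion-review warning with Q1
  false, never a CRSwNP call;
- the IT scale is linear in airway occupancy (grade × 25%), so the
  fractional reduction computed on grades equals the reduction in
  occupancy.

The decision table ships as a CSV asset and is checksum-verified
against an embedded SHA-256 at load, so a silently edited table cannot
change diagnoses. The boolean closed form (CRSwNP ⇔ Q1; DNS ⇔ Q3;
AR ⇔ Q2∧Q4; CRSsNP ⇔ ¬Q1∧Q4∧(¬Q2∨Q5)) is used only as an independent
test oracle, never as the implementation.

## Rule parameters

| parameter | default | meaning |
|---|---|---|
| `it_reduction_threshold` | 0.35 | minimum per-side fractional IT shrinkage counting as a decongestant response; below this, airflow change is within the non-allergic range |
| `inv_pathology_threshold` | 1 | minimum INV grade counting as valve obstruction; the certainty grades ⅓ and ⅔ deliberately fall below it |
| `dns_asymmetry_min_diff` | 1 | minimum post-decongestant \|L − R\| DNS difference; one grade is the smallest expressible asymmetry |
| `polyp_presence_min` | 1 | minimum polyp grade counting as polyps present |
| `polyp_timepoint` | `pre` | Q1 reads pre-decongestant polyp grades (decongestion does not remove polyps); `pre_or_post` is available |

All comparisons are ≥ with a 1e-9 tolerance so that exact thirds and
fractional consensus averages compare predictably.

## Consensus

Per grade slot: drop MISSING, take the unique mode if one exists,
otherwise the mean of the valid grades; if every rater marked the slot
"not visualized", substitute a fallback default. A tie among
most-frequent values is the only way a mode can fail with small panels,
and the tie resolves to the mean. Averages are not rounded back onto
the scale — rounding direction would be arbitrary, and the rules are
well-defined on fractions. The fallback defaults (inv 0, it 1, dns 0,
polyp 0) are the least-pathological values that trigger no question on
their own; they are configurable, and every application of a fallback
or average is recorded in an audit trail. Visual diagnoses are
aggregated by counting votes per condition with a ≥2 threshold.

## Accuracy statistics

Sensitivity and specificity are one-vs-rest per condition, with
"Controls" treated as its own label (gold-positive ⇔ empty gold set).
Intervals default to Wilson score (Clopper–Pearson available) via
statsmodels; Wilson is the default because it has good small-sample
coverage at the stratum sizes typical here (coverage ≥ 93% at n = 14,
p = 0.7 is asserted by simulation). An empty stratum yields a
flagged-undefined result rather than an exception.

The paired comparison is conditional logistic regression for 1:1
matched pairs, which for this design has an exact closed form on the
discordant counts: log OR = ln(n₁₀/n₀₁), SE = √(1/n₁₀ + 1/n₀₁),
two-sided Wald p. Tests verify the closed form against a numerical
maximization of the conditional likelihood. No continuity corrections
are applied. Two methods that never disagree in a stratum are flagged
"identical" (p undefined); one-sided discordance is flagged
"degenerate" since the MLE is infinite.

The power model is the normal-approximation two-group comparison of
proportions at a Cohen-type effect size h: per-group
n = ((z₁₋α/₂ + z_power)/h)² and power = Φ(h·√(n/2) − z₁₋α/₂). At
h = 0.3, α = 0.05 this gives 175 participants for 80% power and 43%
power at n = 71, and the two functions are mutually inverse to ceiling
granularity.

## Inter-rater agreement

Krippendorff's α is computed from the coincidence-matrix formulation
(α = 1 − D_o/D_e) with nominal, ordinal (cumulative-margin squared) and
interval difference functions; units with fewer than two non-missing
ratings are excluded, and fully degenerate data (zero expected
disagreement) is defined as α = 1. Default metrics: ordinal for the
four grading scales, nominal for per-condition diagnosis indicators —
grades are ordered, diagnoses are categorical; both are configurable.
Confidence intervals are a percentile bootstrap resampling *units*
(participants are the sampling units), 1,000 iterations by default,
seeded. Agreement bands: poor < 0.667 ≤ moderate < 0.800 ≤
satisfactory < 1.000 = perfect; the published banding lists 0.667 in
two bands, resolved here by assigning boundary values upward so the
bands partition (−∞, 1].

## Synthetic cohorts

The generator emulates the study design: 71 participants by default,
drawn from the published mix of controls and eleven specific condition
combinations, each with a noiseless "truth" exam that provably maps to
its gold diagnosis (a self-check runs at generation). Multi-condition
sets reachable through several table rows are sampled uniformly over
those rows. Rater panels (default 4) perturb the truth independently
per slot: with probability `noise` (default 0.15) the grade moves one
step on its scale (clipped at the bounds), then with probability
`nv_rate` (default 0.02) it becomes "not visualized". The noise and
missingness rates are stand-ins chosen to produce visible rater
disagreement, not estimates of real rater behaviour.

What the generator does *not* model: real per-condition grade
distributions (unpublished), rater-specific bias or severity, the nasal
cycle, and correlations between scales beyond those the rules impose.
Passing tests therefore demonstrate the correctness of the pipeline's
logic and statistics on data that satisfies the rules by construction —
not clinical performance on real endoscopy.

## Numerical choices and degenerate inputs

- Exact thirds are stored as floats and all scale membership uses a
  1e-9 tolerance.
- Threshold comparisons are ≥ with the same tolerance, so raising a
  threshold can only switch a question off (verified by property test).
- Consensus mode detection groups values by rounding to 9 decimals and
  returns the original representative value.
- `aggregate_exam` output never contains MISSING; rules raise a
  dedicated error naming the question and slot if handed an unresolved
  exam.
- Bootstrap resamples that are incomputable (no pairable unit) are
  skipped and counted; an all-degenerate bootstrap raises.

## Problem sizes used in tests and the acceptance script

Test and acceptance workloads are sized for fast, deterministic runs:
zero-noise recovery at 200 participants × 4 raters, the exhaustive α
oracle over all 4-unit × 3-rater binary matrices (4,096 cases), Wilson
coverage at 10,000 replicates, and 100 random discordant-count tables
for the conditional-likelihood check. These sizes give the properties
room to fail while keeping the whole suite in seconds.

## Known limitations

- Narrative clinical nuances are not rules: a unilateral decongestant
  response has no special pathway to "control", and no probabilistic or
  fuzzy outputs exist by design.
- The per-rater diagnosis route applies the same fallback defaults as
  the consensus route to individual missing grades; whether that is how
  a specialist would resolve their own `NV` entries is unknowable from
  grading data alone, so every application is logged.
- Accuracy on real patient data cannot be reproduced here: the original
  recordings and per-rater gradings are not public, so the evaluation
  layer is validated by construction and simulation instead.
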