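"""Synthetic cohort generator with known gold diagnoses.

Emulates the study design: each participant has a known multi-label
diagnosis (a subset of {AR, CRSsNP, CRSwNP, DNS}, empty = control),
a noiseless "truth" exam whose grades produce exactly that diagnosis
through the rule engine, and a panel of raters whose gradings are the
truth perturbed by symmetric ±1-grade noise and random "not visualized"
missingness.

The default cohort composition reproduces the published study's
condition mix: 71 participants split over controls and eleven specific
condition combinations (see :data:`TABLE3_COMPOSITION`).  The noise
model is a deliberately simple stand-in — independent per-slot
perturbation, clipped at the scale bounds — not an estimate of real
rater behaviour.

Multi-condition diagnoses can arise from several decision-table rows;
the generator picks uniformly among the rows mapping to the requested
set and then solves for consistent grades, so repeated sampling
exercises every row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Union

import numpy as np

from .consensus import RaterPanel
from .errors import ValidationError
from .grading import MISSING, SCALES, ExamGrading, SideGrades
from .rules import (DecisionTable, QuestionVector, RuleParameters,
                    default_table, diagnose, format_diagnosis_set)

__all__ = [
    "TABLE3_COMPOSITION",
    "default_prevalence",
    "composition_summary",
    "CohortSpec",
    "SyntheticCohort",
    "truth_exam_for",
    "generate_cohort",
    "per_rater_diagnoses",
]

#: Published cohort composition: specific condition combination -> count
#: (n = 71; 6 controls + 65 condition-inclusive participants).
TABLE3_COMPOSITION: Dict[FrozenSet[str], int] = {
    frozenset(): 6,
    frozenset({"AR"}): 11,
    frozenset({"CRSsNP"}): 5,
    frozenset({"CRSwNP"}): 9,
    frozenset({"DNS"}): 16,
    frozenset({"AR", "CRSsNP"}): 2,
    frozenset({"AR", "CRSwNP"}): 3,
    frozenset({"AR", "DNS"}): 15,
    frozenset({"CRSsNP", "DNS"}): 1,
    frozenset({"CRSwNP", "DNS"}): 2,
    frozenset({"AR", "CRSsNP", "DNS"}): 1,
    frozenset({"AR", "CRSwNP", "DNS"}): 0,
}


def default_prevalence() -> Dict[FrozenSet[str], float]:
    """Pattern probabilities proportional to the published counts."""
    total = sum(TABLE3_COMPOSITION.values())
    return {k: v / total for k, v in TABLE3_COMPOSITION.items()}


def composition_summary(counts: Optional[Dict[FrozenSet[str], int]] = None) -> dict:
    """Marginal (condition-inclusive) counts and percentages.

    From the specific-combination counts, recompute the controls /
    condition-inclusive split and the "includes X" marginals, each with
    its percentage of the total to one decimal place.
    """
    counts = dict(TABLE3_COMPOSITION if counts is None else counts)
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("empty composition")

    def entry(n):
        return {"n": n, "pct": round(100.0 * n / total, 1)}

    controls = counts.get(frozenset(), 0)
    summary = {
        "total": total,
        "controls": entry(controls),
        "condition_inclusive": entry(total - controls),
        "includes": {},
    }
    for condition in ("AR", "CRSsNP", "CRSwNP", "DNS"):
        n = sum(c for pattern, c in counts.items() if condition in pattern)
        summary["includes"][condition] = entry(n)
    return summary


NoiseSpec = Union[float, Dict[str, float]]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the published study conditions: 71 participants in
    the published condition mix, graded by 4 raters.  ``noise`` is the
    per-slot probability of a ±1-grade perturbation per rater (scalar or
    per-scale mapping) and ``nv_rate`` the per-slot probability that a
    rater marks the structure "not visualized"; both are stand-ins since
    real per-condition grade distributions are unpublished.
    """

    n_participants: int = 71
    prevalence: Optional[Dict[FrozenSet[str], float]] = None
    n_raters: int = 4
    noise: NoiseSpec = 0.15
    nv_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.n_raters < 1:
            raise ValidationError("n_raters must be >= 1")
        prev = self.resolved_prevalence()
        probs = list(prev.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValidationError("prevalence probabilities must lie in [0,1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("prevalence must sum to 1")
        for name in SCALES:
            p = self.noise_for(name)
            if not 0 <= p <= 1:
                raise ValidationError(f"noise for {name} must lie in [0,1]")
        if not 0 <= self.nv_rate <= 1:
            raise ValidationError("nv_rate must lie in [0,1]")

    def resolved_prevalence(self) -> Dict[FrozenSet[str], float]:
        return (default_prevalence() if self.prevalence is None
                else dict(self.prevalence))

    def noise_for(self, scale_name: str) -> float:
        if isinstance(self.noise, dict):
            return float(self.noise.get(scale_name, 0.0))
        return float(self.noise)


@dataclass
class SyntheticCohort:
    """Gold labels, noiseless truth exams and rater panels, by participant."""

    spec: CohortSpec
    gold: Dict[str, FrozenSet[str]]
    truth_exams: Dict[str, ExamGrading]
    panels: Dict[str, RaterPanel]

    @property
    def participants(self) -> List[str]:
        return list(self.gold)


_IT_RESPONSE_PAIRS = ((4, 2), (4, 1), (3, 1), (2, 1))  # reductions >= 0.5
_IT_FLAT_PAIRS = ((1, 1), (2, 2), (3, 3), (4, 4), (4, 3))  # reductions <= 0.25


def _pick(rng: np.random.Generator, options):
    return options[int(rng.integers(len(options)))]


def truth_exam_for(diagnosis: FrozenSet[str], rng: np.random.Generator,
                   table: Optional[DecisionTable] = None,
                   participant_id: str = "truth") -> ExamGrading:
    """Construct a noiseless exam whose rule-engine diagnosis is *diagnosis*.

    Picks uniformly among the decision-table rows mapping to the set,
    then samples grades consistent with that question vector (the five
    questions read disjoint grade slots, so any row is satisfiable).
    """
    table = table or default_table()
    rows = [QuestionVector(*qv) for qv, ds in table.items() if ds == diagnosis]
    if not rows:
        reachable = sorted(format_diagnosis_set(ds)
                           for ds in table.reachable_sets())
        raise ValidationError(
            f"{format_diagnosis_set(diagnosis)!r} is not an output of the "
            f"decision table; reachable sets: {reachable}"
        )
    qv = rows[int(rng.integers(len(rows)))]

    # Q1: bilateral polyps pre (mirrored post — decongestion leaves polyps).
    if qv.q1:
        polyp = {s: float(rng.integers(1, 4)) for s in "LR"}
    else:
        polyp = {"L": 0.0, "R": 0.0}

    # Q2: per-side (pre, post) IT pairs with clear margin around 35%.
    pairs = _IT_RESPONSE_PAIRS if qv.q2 else _IT_FLAT_PAIRS
    it = {s: _pick(rng, pairs) for s in "LR"}

    # Q3: post-decongestant septal asymmetry; pre mirrors post.
    if qv.q3:
        d = int(rng.integers(1, 4))
        hi = int(rng.integers(d, 4))
        lo = hi - d
        dns = {"L": float(hi), "R": float(lo)}
        if rng.random() < 0.5:
            dns = {"L": dns["R"], "R": dns["L"]}
    else:
        v = float(rng.integers(0, 2))
        dns = {"L": v, "R": v}

    # Q4/Q5: INV bilaterally >= 1 or bilaterally in the control range.
    def inv_pair(flag: bool):
        high = (1.0, 2.0)
        low = (0.0, 1.0 / 3.0, 2.0 / 3.0)
        return {s: float(_pick(rng, high if flag else low)) for s in "LR"}

    inv_pre = inv_pair(qv.q4)
    inv_post = inv_pair(qv.q5)

    def side(tp, s):
        return SideGrades(
            inv=inv_pre[s] if tp == "pre" else inv_post[s],
            it=float(it[s][0] if tp == "pre" else it[s][1]),
            dns=dns[s],
            polyp=polyp[s],
        )

    exam = ExamGrading(
        participant_id=participant_id, rater_id="truth",
        pre_left=side("pre", "L"), pre_right=side("pre", "R"),
        post_left=side("post", "L"), post_right=side("post", "R"),
    )
    got = diagnose(exam, RuleParameters(), table)
    if got != diagnosis:  # generator self-check
        raise RuntimeError(
            f"generator self-check failed: wanted "
            f"{format_diagnosis_set(diagnosis)}, rules produced "
            f"{format_diagnosis_set(got)}"
        )
    return exam


def _perturb(value, scale, rng: np.random.Generator,
             noise: float, nv_rate: float):
    if noise > 0 and rng.random() < noise:
        idx = scale.index(value)
        idx = int(np.clip(idx + (1 if rng.random() < 0.5 else -1),
                          0, len(scale.values) - 1))
        value = scale.values[idx]
    if nv_rate > 0 and rng.random() < nv_rate:
        return MISSING
    return value


def _noisy_copy(exam: ExamGrading, rater_id: str, spec: CohortSpec,
                rng: np.random.Generator) -> ExamGrading:
    sides = {}
    for attr in ("pre_left", "pre_right", "post_left", "post_right"):
        sg = getattr(exam, attr)
        grades = {
            name: _perturb(sg.get(name), SCALES[name], rng,
                           spec.noise_for(name), spec.nv_rate)
            for name in SCALES
        }
        sides[attr] = SideGrades(**grades)
    return ExamGrading(participant_id=exam.participant_id,
                       rater_id=rater_id, **sides)


def generate_cohort(spec: CohortSpec = CohortSpec()) -> SyntheticCohort:
    """Sample a cohort: gold patterns, truth exams, noisy rater panels.

    Reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    prev = spec.resolved_prevalence()
    patterns = list(prev)
    probs = np.asarray([prev[p] for p in patterns], dtype=float)
    probs = probs / probs.sum()

    width = max(3, len(str(spec.n_participants)))
    gold, truth_exams, panels = {}, {}, {}
    draws = rng.choice(len(patterns), size=spec.n_participants, p=probs)
    for i, k in enumerate(draws):
        pid = f"P{i + 1:0{width}d}"
        pattern = patterns[int(k)]
        gold[pid] = pattern
        truth = truth_exam_for(pattern, rng, participant_id=pid)
        truth_exams[pid] = truth
        exams = [
            _noisy_copy(truth, f"R{j + 1}", spec, rng)
            for j in range(spec.n_raters)
        ]
        panels[pid] = RaterPanel(exams=exams)
    return SyntheticCohort(spec=spec, gold=gold,
                           truth_exams=truth_exams, panels=panels)


def per_rater_diagnoses(cohort: SyntheticCohort,
                        params: RuleParameters = RuleParameters(),
                        defaults=None) -> Dict[str, List[FrozenSet[str]]]:
    """Run the rule engine on each rater's own grading (rater-specific mode).

    Each rater's MISSING slots are resolved with the fallback defaults
    before diagnosis; returns participant -> one diagnosis per rater.
    """
    from .consensus import FallbackDefaults, aggregate_exam

    defaults = defaults or FallbackDefaults()
    out: Dict[str, List[FrozenSet[str]]] = {}
    for pid, panel in cohort.panels.items():
        votes = []
        for exam in panel.exams:
            resolved = aggregate_exam(RaterPanel(exams=[exam]), defaults)
            votes.append(diagnose(resolved, params))
        out[pid] = votes
    return out
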