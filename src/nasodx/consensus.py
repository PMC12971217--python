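"""Multi-rater consensus aggregation.

Grades from several raters are reduced to one exam per participant with
a three-step rule applied independently to each of the 16 grade slots
(4 scales × 2 sides × 2 timepoints):

1. drop MISSING ("not visualized") ratings;
2. if a unique most-frequent value exists among the rest, take the mode;
3. on a tie for most frequent, take the arithmetic mean of the valid
   grades (with ≤4 raters a tie is the only way a mode can fail to
   exist);
4. if *every* rater marked the slot MISSING, substitute a predefined
   fallback default.

Averages are deliberately not rounded back onto the scale: downstream
rules compare numerically, so fractional consensus grades are
well-defined inputs.

Visual-inspection diagnoses are aggregated separately: a condition is
part of the consensus diagnosis if at least ``min_votes`` raters
(default 2) independently identified it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence

from .errors import ConfigError, ValidationError
from .grading import MISSING, SCALES, SLOTS, ExamGrading, SideGrades
from .rules import CONDITIONS

__all__ = [
    "RaterPanel",
    "FallbackDefaults",
    "AuditEntry",
    "aggregate_grade",
    "aggregate_exam",
    "consensus_visual_diagnosis",
]


@dataclass(frozen=True)
class FallbackDefaults:
    """Per-scale defaults used when all raters marked a slot MISSING.

    The defaults are the least-pathological values that trigger no
    question on their own: inv=0, it=1 at both timepoints (hence zero
    reduction), dns=0, polyp=0.  Absence of evidence must not assert
    pathology.
    """

    inv: float = 0.0
    it: float = 1.0
    dns: float = 0.0
    polyp: float = 0.0

    def __post_init__(self):
        for name in ("inv", "it", "dns", "polyp"):
            scale = SCALES[name]
            if not scale.contains(getattr(self, name)):
                raise ConfigError(
                    f"fallback default for {name} must lie in "
                    f"{list(scale.values)}, got {getattr(self, name)!r}"
                )


@dataclass
class RaterPanel:
    """All raters' exams for one participant."""

    exams: List[ExamGrading]

    def __post_init__(self):
        if not self.exams:
            raise ValidationError("a rater panel needs at least one exam")
        pids = {e.participant_id for e in self.exams}
        if len(pids) != 1:
            raise ValidationError(
                f"panel mixes participants {sorted(pids)}"
            )

    @property
    def participant_id(self) -> str:
        return self.exams[0].participant_id

    @property
    def raters(self) -> List[str]:
        return [e.rater_id for e in self.exams]


@dataclass(frozen=True)
class AuditEntry:
    """Record of which rule resolved one consensus slot."""

    slot: str
    rule: str  # "mode" | "average" | "default"
    value: float


def _aggregate(values: Sequence, default: float):
    valid = [v for v in values if v is not MISSING]
    if not valid:
        return float(default), "default"
    # Group by rounded key so the exact thirds of the INV scale compare
    # reliably; keys map back to the first value seen.
    rep = {}
    counts = Counter()
    for v in valid:
        key = round(float(v), 9)
        rep.setdefault(key, float(v))
        counts[key] += 1
    top = max(counts.values())
    modes = [k for k, c in counts.items() if c == top]
    if len(modes) == 1:
        return rep[modes[0]], "mode"
    return sum(float(v) for v in valid) / len(valid), "average"


def aggregate_grade(values: Sequence, default: float) -> float:
    """Consensus value for one grade slot (mode → mean → default).

    Permutation-invariant in *values*; never returns MISSING.
    """
    if not values:
        raise ValidationError("aggregate_grade needs a non-empty list")
    value, _ = _aggregate(values, default)
    return value


def aggregate_exam(panel: RaterPanel,
                   defaults: FallbackDefaults = FallbackDefaults(),
                   audit: Optional[list] = None) -> ExamGrading:
    """Aggregate a rater panel slot-wise into one consensus exam.

    The result contains no MISSING values.  If *audit* is a list, one
    :class:`AuditEntry` per slot is appended describing the rule applied.
    """
    sides = {}
    for tp, sd, attr in SLOTS:
        grades = {}
        for scale_name in SCALES:
            values = [getattr(e, attr).get(scale_name) for e in panel.exams]
            value, rule = _aggregate(values, getattr(defaults, scale_name))
            grades[scale_name] = value
            if audit is not None:
                audit.append(AuditEntry(f"{attr}.{scale_name}", rule, value))
        sides[attr] = SideGrades(**grades)
    return ExamGrading(
        participant_id=panel.participant_id,
        rater_id="consensus",
        **sides,
    )


def consensus_visual_diagnosis(votes: Sequence[FrozenSet[str]],
                               min_votes: int = 2) -> FrozenSet[str]:
    """Conditions independently identified by ≥ *min_votes* raters.

    The empty result denotes a consensus of Controls.  Monotone: adding
    a vote containing condition C never removes C from the output.
    """
    if min_votes < 1:
        raise ConfigError("min_votes must be at least 1")
    if not votes:
        raise ValidationError("need at least one vote")
    counts = Counter(c for v in votes for c in v)
    return frozenset(c for c in CONDITIONS if counts.get(c, 0) >= min_votes)
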