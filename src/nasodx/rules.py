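"""Five-question rule engine and the 32-row decision table.

The expert system asks five yes/no questions of a fully resolved exam
(no MISSING grades) and maps the resulting boolean vector through an
exhaustive decision table to a multi-label diagnosis:

* **Q1** — nasal polyps present (grade ≥ 1) on *both* sides?  Bilateral
  polyps indicate CRSwNP; unilateral polypoid masses may be neoplastic
  and are flagged for exclusion review, never treated as CRSwNP.
* **Q2** — did the inferior turbinates shrink by ≥ 35% on *both* sides
  after decongestant?  A bilateral response indicates the reversible
  congestion of allergic rhinitis.
* **Q3** — is the post-decongestant septal grading asymmetric between
  the two cavities (≥ 1 grade difference)?  Asymmetry after decongestion
  indicates a deviated septum while cancelling the nasal cycle.
* **Q4 / Q5** — internal nasal valve grade ≥ 1 on both sides before /
  after decongestant?  Persistent valve obstruction separates pathology
  from controls; the certainty grades 1/3 and 2/3 count as below 1.

The table maps all 32 question vectors to subsets of
{AR, CRSsNP, CRSwNP, DNS}; the empty set denotes a control participant.
It ships as a version-controlled CSV asset, checksum-verified at load.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from typing import FrozenSet, NamedTuple, Optional

from .errors import ConfigError, MissingGradeError, ValidationError
from .grading import GRADE_TOL, MISSING, ExamGrading

__all__ = [
    "CONDITIONS",
    "CONTROLS",
    "QuestionVector",
    "RuleParameters",
    "DecisionTable",
    "load_decision_table",
    "format_diagnosis_set",
    "parse_diagnosis_set",
    "q1_bilateral_polyps",
    "q2_decongestant_response",
    "q3_dns_asymmetry",
    "q4_inv_pre",
    "q5_inv_post",
    "evaluate_questions",
    "lookup_diagnosis",
    "diagnose",
]

logger = logging.getLogger(__name__)

#: Canonical serialization order of the condition labels.
CONDITIONS = ("AR", "CRSsNP", "CRSwNP", "DNS")

#: The empty diagnosis set denotes a control participant.
CONTROLS: FrozenSet[str] = frozenset()

DiagnosisSet = FrozenSet[str]


class QuestionVector(NamedTuple):
    """The five boolean question outcomes, in evaluation order."""

    q1: bool  # polyps bilateral
    q2: bool  # bilateral >=35% IT reduction
    q3: bool  # post-decongestant DNS asymmetry
    q4: bool  # bilateral INV >= 1 pre
    q5: bool  # bilateral INV >= 1 post


@dataclass(frozen=True)
class RuleParameters:
    """Tunable thresholds of the rule engine (all ≥-comparisons).

    Attributes
    ----------
    it_reduction_threshold : float
        Minimum per-side fractional IT size reduction for a decongestant
        response (default 0.35).
    inv_pathology_threshold : float
        Minimum INV grade counting as valve obstruction (default 1;
        the certainty grades 1/3 and 2/3 fall below it).
    dns_asymmetry_min_diff : float
        Minimum |left − right| post-decongestant DNS grade difference
        (default 1, the smallest expressible asymmetry; consensus
        averaging can produce fractional differences, compared against
        the same threshold).
    polyp_presence_min : float
        Minimum polyp grade counting as polyps present (default 1).
    polyp_timepoint : str
        Which timepoint Q1 reads: "pre" (default — decongestion does not
        remove polyps and polyps are evaluated first) or "pre_or_post"
        (a side is positive if either timepoint shows polyps).
    """

    it_reduction_threshold: float = 0.35
    inv_pathology_threshold: float = 1.0
    dns_asymmetry_min_diff: float = 1.0
    polyp_presence_min: float = 1.0
    polyp_timepoint: str = "pre"

    def __post_init__(self):
        for name in ("it_reduction_threshold", "inv_pathology_threshold",
                     "dns_asymmetry_min_diff", "polyp_presence_min"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.polyp_timepoint not in ("pre", "pre_or_post"):
            raise ConfigError(
                "polyp_timepoint must be 'pre' or 'pre_or_post'"
            )


def format_diagnosis_set(ds: DiagnosisSet) -> str:
    """Serialize canonically: fixed condition order, '+'-joined; empty → 'Controls'."""
    if not ds:
        return "Controls"
    unknown = set(ds) - set(CONDITIONS)
    if unknown:
        raise ValidationError(f"unknown condition labels {sorted(unknown)}")
    return "+".join(c for c in CONDITIONS if c in ds)


def parse_diagnosis_set(text) -> DiagnosisSet:
    token = str(text).strip()
    if token == "" or token.lower() == "controls":
        return CONTROLS
    parts = [p.strip() for p in token.split("+")]
    for p in parts:
        if p not in CONDITIONS:
            raise ValidationError(
                f"unknown condition label {p!r}; legal labels are "
                f"{list(CONDITIONS)} joined by '+', or 'Controls'"
            )
    return frozenset(parts)


_TABLE_RESOURCE = "decision_table.csv"
_TABLE_SHA256 = "d979bf978f94971de932001ddd87bcc6c3f755590d9be8201073f0a0217094af"


class DecisionTable:
    """Total mapping from all 32 question vectors to diagnosis sets."""

    def __init__(self, mapping: dict):
        if len(mapping) != 32:
            raise ValidationError(
                f"decision table must have exactly 32 rows, got {len(mapping)}"
            )
        self._mapping = dict(mapping)

    def __getitem__(self, qv: QuestionVector) -> DiagnosisSet:
        return self._mapping[tuple(bool(b) for b in qv)]

    def items(self):
        return self._mapping.items()

    def reachable_sets(self) -> set:
        return set(self._mapping.values())


def load_decision_table() -> DecisionTable:
    """Load and checksum-verify the packaged decision-table asset."""
    raw = resources.files("nasodx.data").joinpath(_TABLE_RESOURCE).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE_SHA256:
        raise ValidationError(
            "decision table asset checksum mismatch: the packaged "
            f"{_TABLE_RESOURCE} has been modified (sha256 {digest})"
        )
    mapping = {}
    lines = raw.decode("utf-8").strip().splitlines()
    for line in lines[1:]:
        *qs, diag = line.strip().split(",")
        key = tuple(tok == "T" for tok in qs)
        mapping[key] = parse_diagnosis_set(diag)
    return DecisionTable(mapping)


_DEFAULT_TABLE: Optional[DecisionTable] = None


def default_table() -> DecisionTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_decision_table()
    return _DEFAULT_TABLE


def _resolved(value, slot: str, question: str) -> float:
    if value is MISSING:
        raise MissingGradeError(
            f"{question} needs {slot} but it is MISSING; resolve the exam "
            "with consensus aggregation or fallback defaults first"
        )
    return float(value)


def q1_bilateral_polyps(exam: ExamGrading, params: RuleParameters = RuleParameters()) -> bool:
    """Q1: polyp grade ≥ polyp_presence_min on both sides.

    Unilateral polyps yield False and a logged warning flagging the
    participant for exclusion review (a unilateral mass may be
    neoplastic and needs imaging or histology, not this rule set).
    """
    def side_positive(side: str) -> bool:
        pre = _resolved(exam.side("pre", side).polyp, f"pre_{side}.polyp", "Q1")
        if params.polyp_timepoint == "pre":
            return pre >= params.polyp_presence_min - GRADE_TOL
        post = _resolved(exam.side("post", side).polyp, f"post_{side}.polyp", "Q1")
        return max(pre, post) >= params.polyp_presence_min - GRADE_TOL

    left, right = side_positive("L"), side_positive("R")
    if left != right:
        logger.warning(
            "participant %s: unilateral polypoid finding (L=%s, R=%s); "
            "flagged for exclusion review, not treated as CRSwNP",
            exam.participant_id, left, right,
        )
    return left and right


def q2_decongestant_response(exam: ExamGrading, params: RuleParameters = RuleParameters()) -> bool:
    """Q2: fractional IT reduction ≥ threshold on both sides.

    Reduction is (pre − post)/pre on the grade values; the scale is
    linear in occupancy (grade × 25%), so grade ratios equal occupancy
    ratios.  A side where post > pre counts as zero response.
    """
    for side in ("L", "R"):
        pre = _resolved(exam.side("pre", side).it, f"pre_{side}.it", "Q2")
        post = _resolved(exam.side("post", side).it, f"post_{side}.it", "Q2")
        reduction = max(pre - post, 0.0) / pre
        if reduction < params.it_reduction_threshold - GRADE_TOL:
            return False
    return True


def q3_dns_asymmetry(exam: ExamGrading, params: RuleParameters = RuleParameters()) -> bool:
    """Q3: |left − right| post-decongestant DNS grade ≥ threshold."""
    left = _resolved(exam.side("post", "L").dns, "post_L.dns", "Q3")
    right = _resolved(exam.side("post", "R").dns, "post_R.dns", "Q3")
    return abs(left - right) >= params.dns_asymmetry_min_diff - GRADE_TOL


def _inv_bilateral(exam: ExamGrading, timepoint: str, params: RuleParameters,
                   question: str) -> bool:
    for side in ("L", "R"):
        v = _resolved(exam.side(timepoint, side).inv,
                      f"{timepoint}_{side}.inv", question)
        if v < params.inv_pathology_threshold - GRADE_TOL:
            return False
    return True


def q4_inv_pre(exam: ExamGrading, params: RuleParameters = RuleParameters()) -> bool:
    """Q4: INV ≥ threshold on both sides before decongestant."""
    return _inv_bilateral(exam, "pre", params, "Q4")


def q5_inv_post(exam: ExamGrading, params: RuleParameters = RuleParameters()) -> bool:
    """Q5: INV ≥ threshold on both sides after decongestant."""
    return _inv_bilateral(exam, "post", params, "Q5")


def evaluate_questions(exam: ExamGrading,
                       params: RuleParameters = RuleParameters()) -> QuestionVector:
    """Evaluate all five questions on a fully resolved exam."""
    return QuestionVector(
        q1=q1_bilateral_polyps(exam, params),
        q2=q2_decongestant_response(exam, params),
        q3=q3_dns_asymmetry(exam, params),
        q4=q4_inv_pre(exam, params),
        q5=q5_inv_post(exam, params),
    )


def lookup_diagnosis(qv: QuestionVector,
                     table: Optional[DecisionTable] = None) -> DiagnosisSet:
    """Map a question vector to its diagnosis set (total over all 32 rows)."""
    return (table or default_table())[qv]


def diagnose(exam: ExamGrading, params: RuleParameters = RuleParameters(),
             table: Optional[DecisionTable] = None) -> DiagnosisSet:
    """Full pipeline: evaluate the five questions, then look up the table."""
    return lookup_diagnosis(evaluate_questions(exam, params), table)
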