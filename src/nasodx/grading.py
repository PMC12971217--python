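"""Endoscopic grading scales and domain types for nasal obstruction exams.

Four validated ordinal scales grade the anterior nasal cavity on each side,
before and after topical decongestant (xylometazoline):

* **INV** — internal nasal valve, graded by visibility of the middle
  turbinate: 0 (head of MT clearly seen), 1 (partially blocked),
  2 (cannot be seen at all).  Raters may express uncertainty between
  0 and 1 with the intermediate values 1/3 ("maybe 0") and
  2/3 ("maybe 1").
* **IT** — inferior turbinate size, 1-4, each grade one quartile of the
  airway space occupied (grade × 25%).
* **DNS** — septal deviation, 0 (straight) to 3 (covers more than
  two-thirds of the cavity).
* **Polyp** — nasal polyposis, 0 (none visualized) to 4 (polyps fill the
  entire cavity).

A structure that could not be visualized at all is recorded as the
explicit :data:`MISSING` marker ("NV" in CSV files).  MISSING is distinct
from grade 0: a clear view showing no pathology is 0, an unviewable
structure is MISSING, and downstream consensus rules treat the two
differently.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterator, Union

from .errors import GradeParseError, ValidationError

__all__ = [
    "MISSING",
    "GradeScale",
    "INV_SCALE",
    "IT_SCALE",
    "DNS_SCALE",
    "POLYP_SCALE",
    "SCALES",
    "SideGrades",
    "ExamGrading",
    "Violation",
    "parse_inv_label",
    "format_inv_label",
    "parse_grade",
    "format_grade",
    "validate_exam",
    "it_occupancy_fraction",
]

#: Comparison tolerance for the fractional INV certainty grades (thirds
#: are not exactly representable in binary floating point).
GRADE_TOL = 1e-9


class _MissingType:
    """Singleton marker for a grade the rater could not visualize."""

    _instance = None

    def __new__(cls) -> "_MissingType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __reduce__(self):
        return (_MissingType, ())


MISSING = _MissingType()

#: A grade slot holds either a numeric grade or the MISSING marker.
GradeValue = Union[float, int, _MissingType]


@dataclass(frozen=True)
class GradeScale:
    """A closed ordinal grading scale.

    Parameters
    ----------
    name : str
        Short lower-case identifier, also the CSV column name.
    values : tuple of float
        The legal grade values, in increasing order.
    """

    name: str
    values: tuple

    def contains(self, value) -> bool:
        """True if *value* matches a scale value to within ``GRADE_TOL``."""
        if value is MISSING:
            return False
        try:
            v = float(value)
        except (TypeError, ValueError):
            return False
        return any(abs(v - a) <= GRADE_TOL for a in self.values)

    def canonical(self, value) -> float:
        """Snap *value* onto the exact scale value it matches."""
        v = float(value)
        for a in self.values:
            if abs(v - a) <= GRADE_TOL:
                return a
        raise ValidationError(
            f"{value!r} is not a legal {self.name.upper()} grade; "
            f"legal values are {list(self.values)}"
        )

    def index(self, value) -> int:
        """Rank of *value* on the scale (0 = lowest grade)."""
        v = float(value)
        for i, a in enumerate(self.values):
            if abs(v - a) <= GRADE_TOL:
                return i
        raise ValidationError(f"{value!r} not on the {self.name.upper()} scale")


INV_SCALE = GradeScale("inv", (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0, 2.0))
IT_SCALE = GradeScale("it", (1.0, 2.0, 3.0, 4.0))
DNS_SCALE = GradeScale("dns", (0.0, 1.0, 2.0, 3.0))
POLYP_SCALE = GradeScale("polyp", (0.0, 1.0, 2.0, 3.0, 4.0))

SCALES = {s.name: s for s in (INV_SCALE, IT_SCALE, DNS_SCALE, POLYP_SCALE)}

# Canonical label spellings for the INV certainty scale.
_INV_LABELS = {
    "0": 0.0,
    "maybe 0": 1.0 / 3.0,
    "maybe0": 1.0 / 3.0,
    "1/3": 1.0 / 3.0,
    "maybe 1": 2.0 / 3.0,
    "maybe1": 2.0 / 3.0,
    "2/3": 2.0 / 3.0,
    "1": 1.0,
    "2": 2.0,
}


def parse_inv_label(label, row=None) -> GradeValue:
    """Parse an INV grade label ("0", "maybe 0", "maybe 1", "1", "2", "NV").

    Case-insensitive; internal whitespace is normalized.  "NV" (not
    visualized) parses to :data:`MISSING`.  Round-trips with
    :func:`format_inv_label`.
    """
    token = " ".join(str(label).strip().lower().split())
    if token == "nv":
        return MISSING
    if token in _INV_LABELS:
        return _INV_LABELS[token]
    where = f" (row {row})" if row is not None else ""
    raise GradeParseError(f"unrecognized INV label {label!r}{where}")


def format_inv_label(value) -> str:
    """Inverse of :func:`parse_inv_label` over the 5-point scale + MISSING."""
    if value is MISSING:
        return "NV"
    v = INV_SCALE.canonical(value)
    return {0.0: "0", 1.0 / 3.0: "maybe 0", 2.0 / 3.0: "maybe 1",
            1.0: "1", 2.0: "2"}[v]


def parse_grade(scale: GradeScale, label, row=None) -> GradeValue:
    """Parse any grade cell; dispatches INV to its label parser."""
    if scale.name == "inv":
        return parse_inv_label(label, row=row)
    token = str(label).strip()
    if token.upper() == "NV":
        return MISSING
    try:
        v = float(token)
    except ValueError:
        where = f" (row {row})" if row is not None else ""
        raise GradeParseError(
            f"unrecognized {scale.name.upper()} grade {label!r}{where}"
        ) from None
    if not scale.contains(v):
        where = f" (row {row})" if row is not None else ""
        raise GradeParseError(
            f"{scale.name.upper()} grade {label!r} outside legal domain "
            f"{list(scale.values)}{where}"
        )
    return scale.canonical(v)


def format_grade(scale: GradeScale, value) -> str:
    if scale.name == "inv":
        return format_inv_label(value)
    if value is MISSING:
        return "NV"
    return str(int(scale.canonical(value)))


def it_occupancy_fraction(grade) -> float:
    """Fraction of airway space occupied at an IT grade (grade × 0.25)."""
    if grade is MISSING:
        raise ValidationError(
            "IT grade is MISSING; resolve missingness (consensus/fallback) "
            "before computing occupancy"
        )
    return IT_SCALE.canonical(grade) * 0.25


@dataclass(frozen=True)
class SideGrades:
    """The four scale values for one nostril at one timepoint."""

    inv: GradeValue = MISSING
    it: GradeValue = MISSING
    dns: GradeValue = MISSING
    polyp: GradeValue = MISSING

    def get(self, scale_name: str) -> GradeValue:
        return getattr(self, scale_name)


#: (timepoint, side) -> ExamGrading attribute, in canonical order.
SLOTS = (
    ("pre", "L", "pre_left"),
    ("pre", "R", "pre_right"),
    ("post", "L", "post_left"),
    ("post", "R", "post_right"),
)


@dataclass(frozen=True)
class ExamGrading:
    """One rater's complete L/R × pre/post grading of one participant."""

    participant_id: str
    rater_id: str
    pre_left: SideGrades = SideGrades()
    pre_right: SideGrades = SideGrades()
    post_left: SideGrades = SideGrades()
    post_right: SideGrades = SideGrades()

    def side(self, timepoint: str, side: str) -> SideGrades:
        for tp, sd, attr in SLOTS:
            if tp == timepoint and sd == side:
                return getattr(self, attr)
        raise ValidationError(f"no slot for timepoint={timepoint!r} side={side!r}")

    def grade_slots(self) -> Iterator[tuple]:
        """Yield (slot_name, value, scale) for all 16 grade slots."""
        for _, _, attr in SLOTS:
            sg = getattr(self, attr)
            for f in fields(SideGrades):
                yield f"{attr}.{f.name}", getattr(sg, f.name), SCALES[f.name]


@dataclass(frozen=True)
class Violation:
    """One out-of-domain grade found by :func:`validate_exam`."""

    slot: str
    value: object
    domain: tuple

    def __str__(self) -> str:
        return (
            f"{self.slot}: value {self.value!r} outside legal domain "
            f"{list(self.domain)} (or NV)"
        )


def validate_exam(exam: ExamGrading) -> list:
    """Check every grade slot against its scale's domain.

    Returns a list of :class:`Violation` (empty iff the exam is valid);
    MISSING is always legal.  Violations are data, not exceptions.
    """
    out = []
    for slot, value, scale in exam.grade_slots():
        if value is MISSING or scale.contains(value):
            continue
        out.append(Violation(slot=slot, value=value, domain=scale.values))
    return out
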