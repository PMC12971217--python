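"""CSV / YAML / JSON input-output and run configuration.

File formats
------------
Grading CSV (long format, one row per participant × rater × timepoint ×
side): columns ``participant_id, rater_id, timepoint, side, inv, it,
dns, polyp``; timepoint ∈ {pre, post}, side ∈ {L, R}; "not visualized"
is encoded literally as ``NV``; INV accepts the certainty labels
("maybe 0", "maybe 1").

Diagnosis CSV: ``participant_id, diagnosis`` with conditions "+"-joined
in canonical order and an empty field (or "Controls") for controls; the
per-rater variant adds a ``rater_id`` column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional

import pandas as pd
import yaml

from . import __version__
from .consensus import FallbackDefaults, RaterPanel
from .errors import NasodxError, ValidationError
from .grading import SCALES, SLOTS, ExamGrading, SideGrades, format_grade, parse_grade
from .rules import RuleParameters, format_diagnosis_set, parse_diagnosis_set

__all__ = [
    "GRADING_COLUMNS",
    "RunConfig",
    "read_gradings_csv",
    "write_gradings_csv",
    "read_diagnoses_csv",
    "write_diagnoses_csv",
    "read_rater_diagnoses_csv",
    "write_rater_diagnoses_csv",
    "write_manifest",
]

GRADING_COLUMNS = ["participant_id", "rater_id", "timepoint", "side",
                   "inv", "it", "dns", "polyp"]

_SLOT_ATTR = {(tp, sd): attr for tp, sd, attr in SLOTS}


@dataclass
class RunConfig:
    """Bundle of all tunables a pipeline run depends on."""

    rules: RuleParameters = field(default_factory=RuleParameters)
    defaults: FallbackDefaults = field(default_factory=FallbackDefaults)
    min_votes: int = 2
    ci_method: str = "wilson"
    ci_level: float = 0.95
    n_boot: int = 1000
    effect_size: float = 0.3
    alpha: float = 0.05
    power_target: float = 0.80
    grade_metric: str = "ordinal"
    diagnosis_metric: str = "nominal"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "rules" in kwargs:
            kwargs["rules"] = RuleParameters(**kwargs["rules"])
        if "defaults" in kwargs:
            kwargs["defaults"] = FallbackDefaults(**kwargs["defaults"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ValidationError(f"bad config {path}: {exc}") from None

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_gradings_csv(path) -> Dict[str, RaterPanel]:
    """Read a long-format grading CSV into per-participant rater panels.

    Rows for slots a rater never filed are treated as all-MISSING;
    malformed cells raise with the offending 1-based data row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in GRADING_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(
            f"{path}: missing required columns {missing_cols}"
        )
    # participant -> rater -> (timepoint, side) -> SideGrades
    nested: Dict[str, Dict[str, Dict[tuple, SideGrades]]] = {}
    order: List[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        tp = str(row.timepoint).strip().lower()
        sd = str(row.side).strip().upper()
        if (tp, sd) not in _SLOT_ATTR:
            raise ValidationError(
                f"{path} row {i}: timepoint={row.timepoint!r} "
                f"side={row.side!r} (legal: pre/post, L/R)"
            )
        grades = {
            name: parse_grade(SCALES[name], getattr(row, name), row=i)
            for name in SCALES
        }
        pid, rid = str(row.participant_id), str(row.rater_id)
        if pid not in nested:
            nested[pid] = {}
            order.append(pid)
        nested[pid].setdefault(rid, {})[(tp, sd)] = SideGrades(**grades)

    panels = {}
    for pid in order:
        exams = []
        for rid, slots in nested[pid].items():
            kwargs = {
                attr: slots.get((tp, sd), SideGrades())
                for tp, sd, attr in SLOTS
            }
            exams.append(ExamGrading(participant_id=pid, rater_id=rid,
                                     **kwargs))
        panels[pid] = RaterPanel(exams=exams)
    return panels


def write_gradings_csv(panels: Dict[str, RaterPanel], path) -> None:
    rows = []
    for pid, panel in panels.items():
        for exam in panel.exams:
            for tp, sd, attr in SLOTS:
                sg = getattr(exam, attr)
                rows.append({
                    "participant_id": pid,
                    "rater_id": exam.rater_id,
                    "timepoint": tp,
                    "side": sd,
                    **{name: format_grade(SCALES[name], sg.get(name))
                       for name in SCALES},
                })
    pd.DataFrame(rows, columns=GRADING_COLUMNS).to_csv(path, index=False)


def read_diagnoses_csv(path) -> Dict[str, FrozenSet[str]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("participant_id", "diagnosis"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out[str(row.participant_id)] = parse_diagnosis_set(row.diagnosis)
        except NasodxError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    return out


def write_diagnoses_csv(diagnoses: Dict[str, FrozenSet[str]], path) -> None:
    rows = [{"participant_id": pid,
             "diagnosis": "" if not ds else format_diagnosis_set(ds)}
            for pid, ds in diagnoses.items()]
    pd.DataFrame(rows, columns=["participant_id", "diagnosis"]).to_csv(
        path, index=False)


def read_rater_diagnoses_csv(path) -> Dict[str, Dict[str, FrozenSet[str]]]:
    """Per-rater diagnosis CSV -> participant -> rater -> DiagnosisSet."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("participant_id", "rater_id", "diagnosis"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out: Dict[str, Dict[str, FrozenSet[str]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ds = parse_diagnosis_set(row.diagnosis)
        except NasodxError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
        out.setdefault(str(row.participant_id), {})[str(row.rater_id)] = ds
    return out


def write_rater_diagnoses_csv(votes: Dict[str, Dict[str, FrozenSet[str]]],
                              path) -> None:
    rows = [{"participant_id": pid, "rater_id": rid,
             "diagnosis": "" if not ds else format_diagnosis_set(ds)}
            for pid, raters in votes.items() for rid, ds in raters.items()]
    pd.DataFrame(rows, columns=["participant_id", "rater_id",
                                "diagnosis"]).to_csv(path, index=False)


def write_manifest(path, config: Optional[RunConfig] = None,
                   seed: Optional[int] = None, **extra) -> None:
    """Record everything needed to reproduce an output bit-for-bit."""
    manifest = {"tool": "nasodx", "version": __version__}
    if config is not None:
        manifest["config"] = config.to_dict()
        manifest["config_hash"] = config.config_hash()
    if seed is not None:
        manifest["seed"] = seed
    manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                          encoding="utf-8")
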