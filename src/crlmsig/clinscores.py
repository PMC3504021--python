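"""Clinical risk scores for resected colorectal liver metastases.

Five published points-based prognostic rubrics — Fong, Nordlinger,
Iwatsuki, Mayo (Zakaria) and the Basingstoke index — expressed as
editable YAML files: each criterion is a comparison on one
ClinicalRecord field worth a number of points, and a patient is called
high risk when the total reaches the rubric's threshold (Fong >= 3,
Nordlinger >= 4, Iwatsuki grade >= 3, Mayo >= 2, Basingstoke >= 10).

The dichotomization thresholds follow the validation study this package
models; the component criteria are transcribed from the scores' original
publications and are marked in each YAML file — review them against
those references before clinical use.  Missing inputs (e.g. unknown
hepatoduodenal nodal status) contribute 0 points and clear the
completeness flag, so a rubric can only under-call risk on incomplete
records; criteria that a cohort structurally cannot satisfy (e.g.
extrahepatic disease in a cohort that excludes it) ship disabled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ClinicalRecord
from . import survival as surv

__all__ = [
    "ScoreRubric",
    "ScoreCriterion",
    "ScoreValue",
    "BUILTIN_RUBRICS",
    "load_rubric",
    "score_patient",
    "score_cohort",
    "evaluate_rubrics",
]

BUILTIN_RUBRICS = ("fong", "nordlinger", "iwatsuki", "mayo", "basingstoke")

_MISSING = {"missing", "unknown", "", "nan", "none"}

_OPS = {
    "eq": lambda v, c: v == c,
    "ne": lambda v, c: v != c,
    "gt": lambda v, c: float(v) > c,
    "ge": lambda v, c: float(v) >= c,
    "lt": lambda v, c: float(v) < c,
    "le": lambda v, c: float(v) <= c,
    "in": lambda v, c: v in c,
    "always": lambda v, c: True,
}


@dataclass
class ScoreCriterion:
    label: str
    field: str | None
    op: str
    value: object
    points: int
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown comparator {self.op!r} in criterion {self.label!r}")
        if self.points < 0:
            raise ValueError(f"criterion {self.label!r}: points must be >= 0")


@dataclass
class ScoreRubric:
    name: str
    high_risk_threshold: int
    criteria: list[ScoreCriterion]

    def max_points(self) -> int:
        return sum(c.points for c in self.criteria if c.enabled)


@dataclass
class ScoreValue:
    patient_id: str
    rubric: str
    points: int
    breakdown: dict  # criterion label -> points awarded
    risk_class: str  # {"high", "low"}
    complete: bool


def load_rubric(name_or_path: str | Path) -> ScoreRubric:
    """Load a rubric by built-in name or from a YAML file path."""
    p = Path(str(name_or_path))
    if str(name_or_path) in BUILTIN_RUBRICS:
        ref = importlib.resources.files("crlmsig.rubrics") / f"{name_or_path}.yaml"
        raw = yaml.safe_load(ref.read_text())
    elif p.exists():
        raw = yaml.safe_load(p.read_text())
    else:
        raise ValueError(
            f"unknown rubric {name_or_path!r}; built-ins are {BUILTIN_RUBRICS}"
        )
    crits = [ScoreCriterion(**c) for c in raw["criteria"]]
    return ScoreRubric(
        name=raw["name"],
        high_risk_threshold=int(raw["high_risk_threshold"]),
        criteria=crits,
    )


def _get_field(record, name: str):
    if isinstance(record, ClinicalRecord):
        return getattr(record, name)
    return record[name]  # mapping / pandas Series


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip().lower() in _MISSING


def score_patient(record, rubric: ScoreRubric | str) -> ScoreValue:
    """Evaluate one rubric on one patient.

    ``record`` may be a ClinicalRecord, a mapping or a pandas row.
    Missing criterion inputs award 0 points and set ``complete=False``;
    disabled criteria are skipped without affecting completeness.
    """
    if isinstance(rubric, str):
        rubric = load_rubric(rubric)
    points = 0
    complete = True
    breakdown: dict[str, int] = {}
    for c in rubric.criteria:
        if not c.enabled:
            continue
        if c.op == "always":
            breakdown[c.label] = c.points
            points += c.points
            continue
        v = _get_field(record, c.field)
        if _is_missing(v):
            complete = False
            breakdown[c.label] = 0
            continue
        awarded = c.points if _OPS[c.op](v, c.value) else 0
        breakdown[c.label] = awarded
        points += awarded
    risk = "high" if points >= rubric.high_risk_threshold else "low"
    pid = _get_field(record, "patient_id")
    return ScoreValue(
        patient_id=str(pid),
        rubric=rubric.name,
        points=points,
        breakdown=breakdown,
        risk_class=risk,
        complete=complete,
    )


def score_cohort(clinical: pd.DataFrame, rubric: ScoreRubric | str) -> pd.DataFrame:
    """Score every patient; returns a frame indexed by patient_id with
    ``points``, ``risk_class`` and ``complete``."""
    if isinstance(rubric, str):
        rubric = load_rubric(rubric)
    rows = [score_patient(row, rubric) for _, row in clinical.iterrows()]
    return pd.DataFrame(
        {
            "points": [r.points for r in rows],
            "risk_class": [r.risk_class for r in rows],
            "complete": [r.complete for r in rows],
        },
        index=pd.Index([r.patient_id for r in rows], name="patient_id"),
    )


def evaluate_rubrics(
    clinical: pd.DataFrame, rubrics=BUILTIN_RUBRICS
) -> pd.DataFrame:
    """Survival comparison of high- vs low-risk patients per rubric.

    Dichotomizes each patient at the rubric threshold and compares DFS
    between the classes (Kaplan-Meier / Mantel-Cox log-rank, with the
    hazard ratio of low vs high from a companion Cox fit).  A rubric that
    puts every patient in one class is flagged non-evaluable.  Returns
    one row per rubric: n_high, n_low, hr_low_vs_high with CI, log-rank p
    and the adjusted p across the evaluable rubrics (Benjamini-Hochberg).
    """
    rows = []
    for r in rubrics:
        rub = load_rubric(r) if isinstance(r, str) else r
        scored = score_cohort(clinical, rub)
        n_high = int((scored["risk_class"] == "high").sum())
        n_low = int((scored["risk_class"] == "low").sum())
        row = {"rubric": rub.name, "n_high": n_high, "n_low": n_low, "evaluable": True}
        if n_high == 0 or n_low == 0:
            row.update(
                {"evaluable": False, "hr": np.nan, "hr_lo": np.nan, "hr_hi": np.nan, "p": np.nan}
            )
        else:
            clin = clinical.set_index("patient_id").loc[scored.index]
            # group order (high, low) alphabetically -> HR reported low vs high
            res = surv.logrank_test(
                clin["dfs_months"], clin["event"], scored["risk_class"].to_numpy()
            )
            row.update(
                {
                    "hr": res.hazard_ratio,
                    "hr_lo": res.hr_ci[0],
                    "hr_hi": res.hr_ci[1],
                    "p": res.p_value,
                }
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("rubric")
    ev = out["evaluable"]
    adj = pd.Series(np.nan, index=out.index)
    if ev.any():
        adj[ev] = surv.bh_adjust(out.loc[ev, "p"].to_numpy())
    out["p_adjusted"] = adj
    return out
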