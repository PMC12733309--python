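"""The five-item threshold-sum risk score for lower-limb complications.

The score awards one point for each item whose value is at or above its
threshold (inclusive), summing to an integer total in 0..5, with the default
item set:

    ==============  =========
    item            threshold
    ==============  =========
    dm_duration       4.50
    tyg_whtr          5.78
    sii             334.27
    mlr              80.50
    car               0.20
    ==============  =========

A subject is classified high-risk when the total exceeds the classification
cut-off of 2.5 points, i.e. at 3 or more points.

.. note::
   The published MLR threshold of 80.50 is kept verbatim for fidelity, but it
   is irreconcilable with the monocyte-to-lymphocyte ratio's natural scale
   (cohort medians near 0.2), where it can never be reached; on that scale
   the item contributes 0 for every realistic subject.  A plausible intended
   reading is 0.805 (or a percentage-scale MLR); both are supported through
   the ``mlr_threshold`` override, and neither is asserted as the authors'
   intent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .roc import RocResult, roc_analysis

__all__ = [
    "ScoreItem",
    "ScoreDefinition",
    "ScoreResult",
    "default_score_definition",
    "apply_composite_score",
    "score_cohort",
    "evaluate_score_against_outcome",
]

DEFAULT_THRESHOLDS = {
    "dm_duration": 4.50,
    "tyg_whtr": 5.78,
    "sii": 334.27,
    "mlr": 80.50,  # printed value; see module note on the scale inconsistency
    "car": 0.20,
}

DEFAULT_CLASSIFICATION_CUTOFF = 2.5


@dataclass(frozen=True)
class ScoreItem:
    variable: str
    threshold: float
    orientation: str = "ge"  # "ge": value >= threshold scores the point

    def flag(self, value: float) -> int:
        if self.orientation == "ge":
            return int(value >= self.threshold)
        if self.orientation == "le":
            return int(value <= self.threshold)
        raise ValueError(f"orientation must be 'ge' or 'le', got {self.orientation}")


@dataclass(frozen=True)
class ScoreDefinition:
    """An ordered set of one-point threshold items plus a classification cut-off."""

    items: tuple[ScoreItem, ...]
    classification_cutoff: float = DEFAULT_CLASSIFICATION_CUTOFF
    is_default: bool = True

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("a score needs at least one item")
        if not all(np.isfinite(i.threshold) for i in self.items):
            raise ValueError("item thresholds must be finite")
        if not 0.0 < self.classification_cutoff < len(self.items):
            raise ValueError(
                "classification cut-off must lie strictly between 0 and "
                f"{len(self.items)}"
            )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "items": [
                {"variable": i.variable, "threshold": i.threshold,
                 "orientation": i.orientation}
                for i in self.items
            ],
            "classification_cutoff": self.classification_cutoff,
            "is_default": self.is_default,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreDefinition":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        items = tuple(
            ScoreItem(d["variable"], float(d["threshold"]),
                      d.get("orientation", "ge"))
            for d in payload["items"]
        )
        return cls(
            items=items,
            classification_cutoff=float(
                payload.get("classification_cutoff", DEFAULT_CLASSIFICATION_CUTOFF)
            ),
            is_default=bool(payload.get("is_default", False)),
        )


@dataclass(frozen=True)
class ScoreResult:
    subject_id: str
    item_flags: tuple[int, ...]
    total: int
    classification: str  # "high-risk" | "low-risk"


def default_score_definition(
    mlr_threshold: float | None = None,
) -> ScoreDefinition:
    """The published five-item definition; ``mlr_threshold`` overrides the
    printed 80.50 (a non-default definition is flagged as such)."""
    thresholds = dict(DEFAULT_THRESHOLDS)
    is_default = True
    if mlr_threshold is not None and mlr_threshold != DEFAULT_THRESHOLDS["mlr"]:
        thresholds["mlr"] = float(mlr_threshold)
        is_default = False
    items = tuple(ScoreItem(v, t) for v, t in thresholds.items())
    return ScoreDefinition(items=items, is_default=is_default)


def apply_composite_score(
    values: Mapping[str, float],
    definition: ScoreDefinition | None = None,
    subject_id: str = "",
) -> ScoreResult:
    """Score one subject from a mapping of item variable -> value."""
    definition = definition or default_score_definition()
    flags = []
    for item in definition.items:
        v = values.get(item.variable)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing score item variable: {item.variable}")
        flags.append(item.flag(float(v)))
    total = int(sum(flags))
    cls = "high-risk" if total > definition.classification_cutoff else "low-risk"
    return ScoreResult(subject_id, tuple(flags), total, cls)


def score_cohort(
    data: pd.DataFrame,
    definition: ScoreDefinition | None = None,
) -> pd.DataFrame:
    """Score every subject of a merged cohort+panel frame.

    Returns one row per subject: the five item flags, the total, and the
    high-/low-risk classification.  Subjects missing any item variable get
    a missing total and classification rather than an error.
    """
    definition = definition or default_score_definition()
    rows = []
    for _, r in data.iterrows():
        row: dict[str, object] = {"subject_id": r["subject_id"]}
        try:
            res = apply_composite_score(
                {i.variable: r.get(i.variable) for i in definition.items},
                definition,
                subject_id=str(r["subject_id"]),
            )
        except ValueError:
            for i in definition.items:
                row[f"flag_{i.variable}"] = pd.NA
            row["total"] = pd.NA
            row["classification"] = pd.NA
            rows.append(row)
            continue
        for i, f in zip(definition.items, res.item_flags):
            row[f"flag_{i.variable}"] = f
        row["total"] = res.total
        row["classification"] = res.classification
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_score_against_outcome(
    totals: Sequence[int],
    labels: Sequence[int] | Sequence[bool],
) -> RocResult:
    """ROC evaluation of the integer score totals against one outcome.

    Delegates to the ROC machinery; integer totals give half-integer
    candidate cut-offs.
    """
    return roc_analysis(np.asarray(totals, dtype=float), labels)
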