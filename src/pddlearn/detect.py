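"""Triage of abnormal records: mislabelled, outlier, undecided.

Every record is compared against its original label using the two class
coverage scores s1 (top) and s2 (runner-up):

* **outlier** — every class score <= ``outlier_max`` (default 0.01):
  the record possesses (almost) none of either class's patterns;
* **undecided** — |s1 - s2| < ``undecided_max_diff`` (default 0.001),
  exact ties included: the evidence for the two classes is
  indistinguishable;
* **mislabelled** — the best-covered class differs from the original
  label and the relative difference |s1 - s2| / |s1 + s2| exceeds
  ``mislabel_min_reldiff`` (default 0.1): the pattern evidence
  contradicts the label strongly enough to suggest the other class;
* **normal** otherwise.

The precedence outlier -> undecided -> mislabelled is deliberate: when
both scores are near zero the relative difference is numerically
meaningless, and an exact tie must never be called a mislabel.
Abnormal records are removed, not relabelled, to avoid writing new
incorrect information into the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .discretize import CategoricalDataset
from .scoring import RecordScore

__all__ = ["Thresholds", "ErrorReport", "classify_record", "detect_all",
           "clean_dataset", "relative_difference"]

STATUSES = ("normal", "mislabelled", "outlier", "undecided")


@dataclass(frozen=True)
class Thresholds:
    outlier_max: float = 0.01
    undecided_max_diff: float = 0.001
    mislabel_min_reldiff: float = 0.1

    def __post_init__(self) -> None:
        for name in ("outlier_max", "undecided_max_diff", "mislabel_min_reldiff"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.undecided_max_diff >= self.mislabel_min_reldiff:
            raise ValueError(
                "undecided_max_diff should sit well below mislabel_min_reldiff"
            )


@dataclass
class ErrorReport:
    record_id: object
    status: str
    scores: RecordScore
    original_label: str
    suggested_label: str | None
    relative_difference: float


def relative_difference(s1: float, s2: float) -> float:
    """|s1 - s2| / |s1 + s2|, defined as 0 when both scores are 0."""
    denom = abs(s1 + s2)
    if denom == 0.0:
        return 0.0
    return abs(s1 - s2) / denom


def _top_two(per_class: dict) -> tuple[str, float, str | None, float]:
    ranked = sorted(per_class.items(), key=lambda kv: (-kv[1], kv[0]))
    c1, s1 = ranked[0]
    if len(ranked) > 1:
        c2, s2 = ranked[1]
    else:
        c2, s2 = None, 0.0
    return c1, s1, c2, s2


def classify_record(
    score: RecordScore,
    original_label: str,
    thresholds: Thresholds | None = None,
) -> ErrorReport:
    """Apply the triage rules to one record.

    Multi-class problems use the top two class scores for the undecided
    and mislabel tests.
    """
    th = thresholds or Thresholds()
    if original_label not in score.per_class:
        raise ValueError(
            f"record {score.record_id!r}: original label {original_label!r} "
            "is not a known class"
        )
    c1, s1, _, s2 = _top_two(score.per_class)
    reldiff = relative_difference(s1, s2)
    if all(s <= th.outlier_max for s in score.per_class.values()):
        status, suggested = "outlier", None
    elif abs(s1 - s2) < th.undecided_max_diff:
        status, suggested = "undecided", None
    elif c1 != original_label and reldiff > th.mislabel_min_reldiff:
        status, suggested = "mislabelled", c1
    else:
        status, suggested = "normal", None
    return ErrorReport(
        record_id=score.record_id,
        status=status,
        scores=score,
        original_label=str(original_label),
        suggested_label=suggested,
        relative_difference=reldiff,
    )


def detect_all(
    scores: list[RecordScore],
    labels: pd.Series,
    thresholds: Thresholds | None = None,
) -> tuple[list[ErrorReport], dict]:
    """Triage every record; returns reports and summary counts.

    The summary counts records by status and mislabels by direction
    (original -> suggested label).
    """
    th = thresholds or Thresholds()
    score_ids = {s.record_id for s in scores}
    if score_ids != set(labels.index):
        raise ValueError("scores and labels cover different record sets")
    reports = [classify_record(s, labels.loc[s.record_id], th) for s in scores]
    by_status = {s: 0 for s in STATUSES}
    directions: dict = {}
    for r in reports:
        by_status[r.status] += 1
        if r.status == "mislabelled":
            key = f"{r.original_label}->{r.suggested_label}"
            directions[key] = directions.get(key, 0) + 1
    summary = {
        "n_records": len(reports),
        "by_status": by_status,
        "mislabel_directions": directions,
        "n_removed": sum(
            v for k, v in by_status.items() if k != "normal"
        ),
    }
    return reports, summary


def reports_to_frame(reports: list[ErrorReport]) -> pd.DataFrame:
    classes = sorted(
        {c for r in reports for c in r.scores.per_class}
    )
    rows = []
    for r in reports:
        row = {"record_id": r.record_id, "status": r.status}
        for c in classes:
            row[f"score_{c}"] = r.scores.per_class.get(c, 0.0)
        row["relative_difference"] = r.relative_difference
        row["original_label"] = r.original_label
        row["suggested_label"] = r.suggested_label or ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("record_id")


def clean_dataset(
    dataset: CategoricalDataset, reports: list[ErrorReport]
) -> tuple[CategoricalDataset, list]:
    """Remove every non-normal record; returns (cleaned, removed IDs)."""
    covered = {r.record_id for r in reports}
    missing = set(dataset.record_ids) - covered
    if missing:
        raise ValueError(f"reports do not cover {len(missing)} record(s)")
    removed = [r.record_id for r in reports if r.status != "normal"]
    return dataset.drop_records(removed), removed
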