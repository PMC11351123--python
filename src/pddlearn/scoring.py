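"""Per-class pattern-coverage scores and unsupervised cluster assignment.

A record's coverage score for class c, written #ID-Class, is the mean
over c's DSUs with a nonzero possession count of #ID-DSU / #CP-DSU (the
fraction of that unit's comprehensive patterns the record possesses).
Zero-count DSUs are excluded from the mean so that one uncovered unit
cannot wipe out the score; a record covered by no DSU of a class scores
0 for it and is flagged uncovered.  Records are clustered by assigning
each to the class with the highest coverage score; exact ties get a
sentinel resolved by the downstream triage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)

from .patterns import PatternCounts, _code_str

__all__ = ["TIE", "UNCOVERED", "RecordScore", "score_record", "score_all",
           "assign_cluster", "evaluate_clustering"]

TIE = "__tie__"
UNCOVERED = "__uncovered__"


@dataclass
class RecordScore:
    record_id: object
    per_class: dict                      # class -> #ID-Class in [0, 1]
    covered_dsus: dict = field(default_factory=dict)  # class -> [codes]
    uncovered: bool = False


def score_record(
    counts: dict,
    cp_totals: dict,
    class_map: dict,
    record_id=None,
    classes=None,
) -> RecordScore:
    """Coverage scores for one record.

    Parameters
    ----------
    counts : mapping DSU code -> #ID-DSU for this record
    cp_totals : mapping DSU code -> #CP-DSU
    class_map : mapping DSU code -> class name or None (class-less DSUs
        contribute to no score)
    classes : iterable of class names, optional
        Classes to score even when no DSU is associated with them (they
        score 0, flagged uncovered); default: the classes present in
        ``class_map``.
    """
    if classes is None:
        classes = sorted({c for c in class_map.values() if c is not None})
    else:
        classes = sorted(str(c) for c in classes)
    per_class: dict = {}
    covered: dict = {}
    for cls in classes:
        fracs = []
        codes = []
        for code, assoc in class_map.items():
            if assoc != cls:
                continue
            total = cp_totals.get(code, 0)
            if total <= 0:
                continue  # nothing to cover in this unit
            cnt = counts.get(code, 0)
            if cnt > 0:
                fracs.append(cnt / total)
                codes.append(code)
        per_class[cls] = float(np.mean(fracs)) if fracs else 0.0
        covered[cls] = codes
    uncovered = all(not v for v in covered.values())
    return RecordScore(
        record_id=record_id, per_class=per_class, covered_dsus=covered,
        uncovered=uncovered,
    )


def score_all(pattern_counts: PatternCounts, class_map: dict,
              classes=None) -> list[RecordScore]:
    """Score every record of a possession-count matrix."""
    cmap = {_code_str(k) if isinstance(k, tuple) else k: v
            for k, v in class_map.items()}
    totals = {_code_str(k) if isinstance(k, tuple) else k: v
              for k, v in pattern_counts.cp_totals.items()}
    frame = pattern_counts.record_counts
    out = []
    for rid, row in frame.iterrows():
        out.append(
            score_record(row.to_dict(), totals, cmap, record_id=rid,
                         classes=classes)
        )
    return out


def assign_cluster(score: RecordScore) -> str:
    """Argmax-class assignment; exact ties -> :data:`TIE`, no coverage at
    all -> :data:`UNCOVERED` (routed to outlier triage downstream)."""
    if not score.per_class or score.uncovered:
        return UNCOVERED
    best = max(score.per_class.values())
    winners = [c for c, s in score.per_class.items() if s == best]
    if len(winners) > 1:
        return TIE
    return winners[0]


def evaluate_clustering(
    assigned,
    reference,
    positive_class: str | None = None,
) -> dict:
    """Accuracy, balanced accuracy, precision, recall, weighted F1.

    Clusters are already class-named, so matching is the identity.
    Sentinel assignments (ties, uncovered records) count as wrong for
    every class.  For binary problems precision/recall refer to
    ``positive_class`` (default: the minority reference class); for
    multi-class problems they are macro-averaged.
    """
    assigned = pd.Series(list(assigned)).astype(str)
    reference = pd.Series(list(reference)).astype(str)
    if len(assigned) != len(reference):
        raise ValueError("assigned and reference label sets differ in size")
    classes = sorted(reference.unique())
    if len(classes) == 2:
        if positive_class is None:
            positive_class = reference.value_counts().idxmin()
        # one-vs-rest on the positive class; sentinel assignments are "rest"
        pos = str(positive_class)
        bin_ref = (reference == pos).map({True: pos, False: "rest"})
        bin_asg = (assigned == pos).map({True: pos, False: "rest"})
        avg_kw = {"pos_label": pos, "average": "binary"}
        prec = precision_score(bin_ref, bin_asg, zero_division=0, **avg_kw)
        rec = recall_score(bin_ref, bin_asg, zero_division=0, **avg_kw)
    else:
        prec = precision_score(reference, assigned, labels=classes,
                               average="macro", zero_division=0)
        rec = recall_score(reference, assigned, labels=classes,
                           average="macro", zero_division=0)
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="y_pred contains classes")
        return {
            "accuracy": float(accuracy_score(reference, assigned)),
            "balanced_accuracy": float(
                balanced_accuracy_score(reference, assigned)
            ),
            "precision": float(prec),
            "recall": float(rec),
            "weighted_f1": float(
                f1_score(reference, assigned, labels=classes,
                         average="weighted", zero_division=0)
            ),
        }
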