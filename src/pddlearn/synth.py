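"""Synthetic categorical datasets with planted class structure and errors.

The generator emulates the shape of an imbalanced clinical table after
discretization: a minority class at 24.4% prevalence, a block of signal
attributes whose category distribution is class-conditional, a block of
pure-noise attributes, and three kinds of planted abnormality with full
ground truth:

* **mislabelled** records keep their class-typical attribute profile and
  only the recorded label is flipped — detectable precisely because the
  pattern evidence contradicts the label;
* **outliers** draw every attribute uniformly, matching neither class
  profile;
* **ambiguous** records draw each signal attribute from a 50/50 mixture
  of the two class profiles.

For a signal attribute with k categories and signal strength s, the
class-preferred category has probability (1 - s)/k + s and every other
category (1 - s)/k; s = 0 collapses to the uniform null and s = 1 makes
the attribute deterministic.  Default sizes (2000 records, 10 signal +
10 noise attributes, 3 categories, mislabel 10% / outlier 1% /
ambiguous 2%, s = 0.6) are desk-scale.  The output is bit-for-bit
reproducible under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .discretize import CategoricalDataset

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "benchmark_detection"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_records: int = 2000
    n_signal_attrs: int = 10
    n_noise_attrs: int = 10
    categories_per_attr: int = 3
    classes: tuple = ("sepsis", "other")
    prevalence: tuple = (0.244, 0.756)
    signal_strength: float = 0.6
    mislabel_rate: float = 0.10
    outlier_rate: float = 0.01
    ambiguous_rate: float = 0.02
    seed: int = 0
    label_attribute: str = "class"

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.prevalence):
            raise ValueError("classes and prevalence differ in length")
        if abs(sum(self.prevalence) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        rates = self.mislabel_rate + self.outlier_rate + self.ambiguous_rate
        if rates >= 1.0:
            raise ValueError("abnormality rates must sum to < 1")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.n_records < 1 or self.categories_per_attr < 2:
            raise ValueError("need >= 1 record and >= 2 categories")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classes"] = list(self.classes)
        d["prevalence"] = list(self.prevalence)
        return d


@dataclass
class GroundTruth:
    table: pd.DataFrame            # record_id-indexed: true_class, planted_status
    preferred: dict = field(default_factory=dict)  # (class, attr) -> category

    @property
    def true_class(self) -> pd.Series:
        return self.table["true_class"]

    @property
    def planted_status(self) -> pd.Series:
        return self.table["planted_status"]


def _class_probs(k: int, pref: int, s: float) -> np.ndarray:
    p = np.full(k, (1.0 - s) / k)
    p[pref] += s
    return p


def generate(spec: SyntheticSpec) -> tuple[CategoricalDataset, GroundTruth]:
    """Draw one dataset and its ground truth from the stated world."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    k = spec.categories_per_attr
    cats = [f"c{i + 1}" for i in range(k)]
    signal_attrs = [f"s{i + 1:02d}" for i in range(spec.n_signal_attrs)]
    noise_attrs = [f"n{i + 1:02d}" for i in range(spec.n_noise_attrs)]
    record_ids = [f"r{i + 1:05d}" for i in range(n)]

    # distinct preferred category per class and signal attribute
    preferred: dict = {}
    pref_idx: dict = {}
    for attr in signal_attrs:
        picks = rng.choice(k, size=len(spec.classes), replace=False)
        for cls, p in zip(spec.classes, picks):
            preferred[(cls, attr)] = cats[int(p)]
            pref_idx[(cls, attr)] = int(p)

    # exact class counts by prevalence, shuffled
    counts = [int(round(p * n)) for p in spec.prevalence]
    counts[-1] = n - sum(counts[:-1])
    true_class = np.repeat(np.array(spec.classes, dtype=object), counts)
    rng.shuffle(true_class)

    # exact planted-status counts, shuffled positions
    n_mis = int(round(spec.mislabel_rate * n))
    n_out = int(round(spec.outlier_rate * n))
    n_amb = int(round(spec.ambiguous_rate * n))
    status = np.array(
        ["mislabelled"] * n_mis + ["outlier"] * n_out
        + ["ambiguous"] * n_amb + ["clean"] * (n - n_mis - n_out - n_amb),
        dtype=object,
    )
    rng.shuffle(status)

    columns: dict = {}
    for attr in signal_attrs:
        col = np.empty(n, dtype=object)
        for cls in spec.classes:
            probs = _class_probs(k, pref_idx[(cls, attr)], spec.signal_strength)
            mask = (true_class == cls) & (status != "outlier") & (status != "ambiguous")
            col[mask] = rng.choice(cats, size=int(mask.sum()), p=probs)
        out_mask = status == "outlier"
        col[out_mask] = rng.choice(cats, size=int(out_mask.sum()))
        amb_mask = status == "ambiguous"
        if amb_mask.any() and len(spec.classes) >= 2:
            m = int(amb_mask.sum())
            src = rng.choice(len(spec.classes), size=m)  # 50/50 class mixture
            vals = np.empty(m, dtype=object)
            for ci, cls in enumerate(spec.classes):
                probs = _class_probs(k, pref_idx[(cls, attr)], spec.signal_strength)
                sel = src == ci
                vals[sel] = rng.choice(cats, size=int(sel.sum()), p=probs)
            col[amb_mask] = vals
        columns[attr] = col
    for attr in noise_attrs:
        columns[attr] = rng.choice(cats, size=n)

    # mislabels: flip the recorded label only
    observed = true_class.copy()
    others = {
        cls: [c for c in spec.classes if c != cls] for cls in spec.classes
    }
    for i in np.flatnonzero(status == "mislabelled"):
        pool = others[true_class[i]]
        observed[i] = pool[int(rng.integers(len(pool)))]
    columns[spec.label_attribute] = observed

    data = pd.DataFrame(columns, index=pd.Index(record_ids, name="record_id"))
    dataset = CategoricalDataset(data, spec.label_attribute)
    gt = GroundTruth(
        table=pd.DataFrame(
            {"true_class": true_class, "planted_status": status},
            index=data.index,
        ),
        preferred=preferred,
    )
    return dataset, gt


def _status_metrics(predicted: pd.Series, planted: pd.Series, label: str,
                    planted_label: str) -> dict:
    pred = predicted == label
    true = planted == planted_label
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    return {
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "n_predicted": int(pred.sum()),
        "n_planted": int(true.sum()),
    }


def benchmark_detection(
    spec: SyntheticSpec,
    thresholds=None,
    **pdd_params,
) -> dict:
    """Run the full pipeline on one generated dataset and score it
    against the ground truth.

    Reports precision/recall for each planted abnormality and the
    clustering balanced accuracy against the true classes.
    """
    from .pipeline import PDD
    from .scoring import evaluate_clustering

    dataset, gt = generate(spec)
    model = PDD(**pdd_params)
    if thresholds is not None:
        model.set_params(thresholds=thresholds)
    X = dataset.data[dataset.feature_attributes]
    y = dataset.labels()
    model.fit(X, y)
    reports, summary = model.detect(X, y)
    status = pd.Series(
        {r.record_id: r.status for r in reports}
    ).loc[gt.table.index]
    assigned = pd.Series(model.predict(X), index=gt.table.index)
    metrics = {
        "mislabel": _status_metrics(status, gt.planted_status,
                                    "mislabelled", "mislabelled"),
        "outlier": _status_metrics(status, gt.planted_status,
                                   "outlier", "outlier"),
        "ambiguous": _status_metrics(status, gt.planted_status,
                                     "undecided", "ambiguous"),
        "clustering": evaluate_clustering(assigned, gt.true_class),
        "summary": summary,
    }
    return metrics
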