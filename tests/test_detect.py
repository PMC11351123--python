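import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pddlearn.detect import (
    Thresholds,
    classify_record,
    clean_dataset,
    detect_all,
    relative_difference,
)
from pddlearn.scoring import RecordScore
from .conftest import make_dataset


def score(sepsis, other, rid="x"):
    return RecordScore(record_id=rid,
                       per_class={"sepsis": sepsis, "other": other},
                       covered_dsus={"sepsis": [], "other": []},
                       uncovered=(sepsis == 0 and other == 0))


@pytest.mark.parametrize(
    "sepsis,other,label,status,suggested",
    [
        # record m: 1/100 and 1/200 coverage -> both below 1% -> outlier
        (0.01, 0.005, "sepsis", "outlier", None),
        # record k: equal evidence for both classes -> undecided
        (0.55, 0.55, "sepsis", "undecided", None),
        # record n: labelled sepsis but covered as other, rel diff 0.149
        (0.5, 0.675, "sepsis", "mislabelled", "other"),
        # same scores with the matching label are normal
        (0.5, 0.675, "other", "normal", None),
        # deep outlier 5510: means ~0.0095 / ~0.0083
        (0.0095, 0.0083, "sepsis", "outlier", None),
        # difference just under the undecided gate
        (0.5005, 0.5, "other", "undecided", None),
        # argmax matches label -> normal regardless of margin
        (0.9, 0.1, "sepsis", "normal", None),
        # argmax differs but relative difference too small -> normal
        (0.50, 0.52, "sepsis", "normal", None),
    ],
)
def test_triage_rules(sepsis, other, label, status, suggested):
    report = classify_record(score(sepsis, other), label)
    assert report.status == status
    assert report.suggested_label == suggested


def test_record_n_relative_difference():
    report = classify_record(score(0.5, 0.675), "sepsis")
    assert report.relative_difference == pytest.approx(0.175 / 1.175, abs=1e-6)
    assert report.relative_difference > 0.1


def test_relative_difference_zero_when_both_zero():
    assert relative_difference(0.0, 0.0) == 0.0
    report = classify_record(score(0.0, 0.0), "sepsis")
    assert report.status == "outlier"


def test_unknown_label_rejected():
    with pytest.raises(ValueError, match="known class"):
        classify_record(score(0.4, 0.2), "not-a-class")


def test_threshold_validation():
    with pytest.raises(ValueError):
        Thresholds(outlier_max=0.0)
    with pytest.raises(ValueError):
        Thresholds(undecided_max_diff=0.2, mislabel_min_reldiff=0.1)


@settings(max_examples=200, deadline=None)
@given(s1=st.floats(0, 1), s2=st.floats(0, 1))
def test_precedence_is_total(s1, s2):
    """Every score pair maps to exactly one status."""
    report = classify_record(score(s1, s2), "sepsis")
    assert report.status in ("normal", "mislabelled", "outlier", "undecided")
    if report.status == "mislabelled":
        assert report.suggested_label == "other"
        assert report.relative_difference > 0.1


def _statuses(scores, labels, **kw):
    reports, _ = detect_all(scores, labels, Thresholds(**kw))
    return pd.Series({r.record_id: r.status for r in reports})


def test_threshold_monotonicity(rng):
    scores = [score(rng.uniform(), rng.uniform(), rid=i) for i in range(300)]
    labels = pd.Series(rng.choice(["sepsis", "other"], 300),
                       index=range(300))
    lo = _statuses(scores, labels, outlier_max=0.01)
    hi = _statuses(scores, labels, outlier_max=0.2)
    assert (hi == "outlier").sum() >= (lo == "outlier").sum()
    strict = _statuses(scores, labels, mislabel_min_reldiff=0.4)
    lax = _statuses(scores, labels, mislabel_min_reldiff=0.1)
    assert (strict == "mislabelled").sum() <= (lax == "mislabelled").sum()


def test_detect_all_summary_directions():
    scores = [score(0.6, 0.1, "a"), score(0.1, 0.6, "b"), score(0.4, 0.4, "c")]
    labels = pd.Series({"a": "other", "b": "sepsis", "c": "other"})
    reports, summary = detect_all(scores, labels)
    assert summary["by_status"] == {
        "normal": 0, "mislabelled": 2, "outlier": 0, "undecided": 1
    }
    assert summary["mislabel_directions"] == {
        "other->sepsis": 1, "sepsis->other": 1
    }
    assert summary["n_removed"] == 3


def test_detect_all_requires_aligned_records():
    with pytest.raises(ValueError, match="record sets"):
        detect_all([score(0.5, 0.5, "a")], pd.Series({"b": "sepsis"}))


class TestCleanDataset:
    def make(self, n):
        return make_dataset(
            [{"a": "x", "class": "sepsis"} for _ in range(n)],
            ids=[f"r{i}" for i in range(n)],
        )

    def test_removal_arithmetic(self):
        ds = self.make(10)
        reports = [classify_record(score(0.6, 0.1, f"r{i}"), "sepsis")
                   for i in range(7)]
        reports += [classify_record(score(0.001, 0.001, f"r{i}"), "sepsis")
                    for i in range(7, 10)]
        cleaned, removed = clean_dataset(ds, reports)
        assert cleaned.n_records == 7 and len(removed) == 3

    def test_identity_when_all_normal(self):
        ds = self.make(4)
        reports = [classify_record(score(0.6, 0.1, f"r{i}"), "sepsis")
                   for i in range(4)]
        cleaned, removed = clean_dataset(ds, reports)
        assert cleaned.n_records == 4 and removed == []

    def test_uncovered_records_rejected(self):
        ds = self.make(3)
        reports = [classify_record(score(0.6, 0.1, "r0"), "sepsis")]
        with pytest.raises(ValueError, match="cover"):
            clean_dataset(ds, reports)


def test_retained_count_identity(default_world, fitted_default):
    """retained = total - (mislabelled + outliers + undecided)."""
    _, dataset, _ = default_world
    X = dataset.data[dataset.feature_attributes]
    reports, summary = fitted_default.detect(X, dataset.labels())
    cleaned, removed = clean_dataset(dataset, reports)
    assert cleaned.n_records == dataset.n_records - summary["n_removed"]
    assert len(removed) == summary["n_removed"]
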