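"""scikit-learn style estimators tying the pipeline together.

:class:`TableDiscretizer` is a transformer turning a mixed-type table
into an all-categorical one; :class:`PDD` fits the full pattern
discovery and disentanglement pipeline (SR-matrix -> spectral
disentanglement -> pattern growth -> knowledge base) and exposes
``transform`` (records x DSUs pattern-count matrix), ``predict``
(unsupervised cluster labels), and ``detect`` (abnormal-record triage).
Both follow sklearn conventions: constructor parameters are stored
verbatim, fitted state carries a trailing underscore, and
``get_params``/``set_params`` come from ``BaseEstimator``.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import patterns as pat_mod
from . import scoring as score_mod
from . import sr_matrix as sr_mod
from .discretize import CategoricalDataset, apply_schemes
from .disentangle import disentangle as _disentangle, refine_entities as _refine_entities
from .detect import Thresholds, clean_dataset as _clean_dataset, detect_all as _detect_all
from .knowledge_base import assemble as _assemble

__all__ = ["TableDiscretizer", "PDD"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(X)


class TableDiscretizer(TransformerMixin, BaseEstimator):
    """Discretize numeric columns of a table into categories.

    Parameters
    ----------
    schemes : dict of column -> BinningScheme, optional
        Clinician-defined or preset schemes.  Columns without a scheme
        get equal-frequency binning when numeric and pass through
        otherwise.
    n_bins : int, default 3
        Equal-frequency bin count for unconfigured numeric columns.

    Attributes
    ----------
    schemes_ : dict
        Realized schemes (with fitted cut points), reusable verbatim.
    """

    def __init__(self, schemes: dict | None = None, n_bins: int = 3):
        self.schemes = schemes
        self.n_bins = n_bins

    def fit(self, X, y=None):
        X = _as_frame(X)
        ds = apply_schemes(
            X.assign(__label__="_"), dict(self.schemes or {}),
            label_attribute="__label__", default_n_bins=self.n_bins,
        )
        self.schemes_ = {k: v for k, v in ds.schemes.items() if k != "__label__"}
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "schemes_"):
            raise NotFittedError("TableDiscretizer is not fitted")
        X = _as_frame(X)
        ds = apply_schemes(
            X.assign(__label__="_"), self.schemes_,
            label_attribute="__label__", default_n_bins=self.n_bins,
        )
        return ds.data.drop(columns="__label__")

    def get_feature_names_out(self, input_features=None):
        return self.feature_names_in_


class PDD(BaseEstimator):
    """Pattern Discovery and Disentanglement.

    Fits an interpretable knowledge base of disentangled association
    patterns from a categorical table and a class label, clusters
    records by pattern coverage, and triages records whose pattern
    evidence contradicts their label.

    Parameters
    ----------
    sr_threshold : float, default 1.96
        Significance gate on adjusted standardized residuals (the 95%
        normal quantile).
    include_label : bool, default True
        Whether label AVs enter the SR-matrix (giving DSUs a direct
        class association); False runs fully label-blind.
    linkage : str, default "average"
        Linkage for the entity-overlap subdivision.
    cut_distance : float, default 0.8
        Tree cut on the (1 - Jaccard) dendrogram.
    class_margin : float, default 0.1
        Enrichment over global prevalence required to associate a
        label-free DSU with a class.
    min_support : int or None
        Minimum support for pattern growth; None means max(5, 0.5% N).
    max_order : int, default 5
        Largest pattern size grown.
    min_class_patterns : float or int, default 0.05
        Floor on a DSU's comprehensive-pattern count for its class
        association to enter the coverage scores: a fraction in (0, 1)
        is relative to the largest same-class unit, an integer >= 1 is
        absolute.  A unit with a handful of patterns makes the per-unit
        fraction a coarse 0/1 vote that swamps the mean; the relative
        default keeps the scores scale-free.  Filtered units stay in
        the knowledge base.
    positive_class : str or None
        Class whose group is numbered #Group 1 and used for binary
        precision/recall.
    thresholds : Thresholds or None
        Triage thresholds; None means the defaults (0.01, 0.001, 0.1).
    label_name : str, default "class"
        Name given to the label attribute when ``y`` is unnamed.

    Attributes
    ----------
    sr_matrix_ : SRMatrix
    decomposition_ : PCDecomposition
    dsus_ : list of DSU
    knowledge_base_ : KnowledgeBase
    classes_ : ndarray of class names
    """

    def __init__(
        self,
        sr_threshold: float = 1.96,
        include_label: bool = True,
        linkage: str = "average",
        cut_distance: float = 0.8,
        class_margin: float = 0.1,
        min_support: int | None = None,
        max_order: int = 5,
        min_class_patterns: float = 0.05,
        positive_class: str | None = None,
        thresholds: Thresholds | None = None,
        label_name: str = "class",
    ):
        self.sr_threshold = sr_threshold
        self.include_label = include_label
        self.linkage = linkage
        self.cut_distance = cut_distance
        self.class_margin = class_margin
        self.min_support = min_support
        self.max_order = max_order
        self.min_class_patterns = min_class_patterns
        self.positive_class = positive_class
        self.thresholds = thresholds
        self.label_name = label_name

    # -- helpers -------------------------------------------------------
    def _dataset(self, X, y) -> CategoricalDataset:
        X = _as_frame(X)
        if y is None:
            raise ValueError("PDD.fit requires the label column y")
        y = pd.Series(np.asarray(y, dtype=object), index=X.index,
                      name=self.label_name)
        if y.name in X.columns:
            raise ValueError(f"X already contains a column {y.name!r}")
        frame = X.copy()
        frame[y.name] = y
        return CategoricalDataset(frame, label_attribute=str(y.name))

    def _check_fitted(self):
        if not hasattr(self, "knowledge_base_"):
            raise NotFittedError("PDD is not fitted; call fit(X, y) first")

    def _effective_min_support(self, n: int) -> int:
        if self.min_support is None:
            return pat_mod.default_min_support(n)
        if not isinstance(self.min_support, numbers.Integral) or self.min_support < 1:
            raise ValueError("min_support must be a positive integer or None")
        return int(self.min_support)

    def _scoring_class_map(self) -> dict:
        """Class-associated DSUs whose pattern counts clear the floor."""
        kb = self.knowledge_base_
        totals = kb.data_space.cp_totals
        if 0 < self.min_class_patterns < 1:
            largest = {}
            for code, cls in kb.class_map.items():
                if cls is not None:
                    largest[cls] = max(largest.get(cls, 0), totals.get(code, 0))
            # never price a class's largest unit out of its own score
            floor = {c: min(max(2, self.min_class_patterns * m), m) if m else 1
                     for c, m in largest.items()}
        elif self.min_class_patterns >= 1:
            floor = None
        else:
            raise ValueError("min_class_patterns must be positive")
        out = {}
        for code, cls in kb.class_map.items():
            if cls is None:
                continue
            limit = self.min_class_patterns if floor is None else floor[cls]
            if totals.get(code, 0) >= limit:
                out[code] = cls
        return out

    # -- estimator API -------------------------------------------------
    def fit(self, X, y):
        """Discover the knowledge base from records ``X`` and labels ``y``."""
        dataset = self._dataset(X, y)
        self.label_attribute_ = dataset.label_attribute
        self.classes_ = np.asarray(dataset.classes, dtype=object)
        sr = sr_mod.build_sr_matrix(dataset, include_label=self.include_label)
        dsus, decomp = _disentangle(
            sr,
            dataset,
            threshold=self.sr_threshold,
            linkage_method=self.linkage,
            cut_distance=self.cut_distance,
            class_margin=self.class_margin,
            positive_class=self.positive_class,
        )
        ms = self._effective_min_support(dataset.n_records)
        Xind = sr_mod.indicator_matrix(dataset.data, sr.index)
        patterns_by_dsu = {
            tuple(d.code): pat_mod.grow_patterns(
                d, dataset, sr, min_support=ms, max_order=self.max_order,
                threshold=self.sr_threshold, X=Xind,
            )
            for d in dsus
        }
        counts = pat_mod.count_patterns(patterns_by_dsu, dataset, sr, X=Xind)
        _refine_entities(dsus, counts, dataset, sr, margin=self.class_margin)
        self.sr_matrix_ = sr
        self.decomposition_ = decomp
        self.dsus_ = dsus
        self.min_support_ = ms
        self.knowledge_base_ = _assemble(
            dsus, patterns_by_dsu, counts, config=self.get_params(deep=False)
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        """Records x DSUs comprehensive-pattern possession counts."""
        self._check_fitted()
        X = _as_frame(X)
        data = X.astype(str)
        Xind = sr_mod.indicator_matrix(data, self.sr_matrix_.index)
        kb = self.knowledge_base_
        codes = sorted(kb.pattern_space.keys())
        counts = np.zeros((len(data), len(codes)), dtype=np.int64)
        for j, code in enumerate(codes):
            for p in kb.pattern_space[code]:
                counts[:, j] += Xind[:, list(p.avs)].all(axis=1)
        return pd.DataFrame(
            counts, index=data.index,
            columns=[pat_mod._code_str(c) for c in codes],
        )

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def score_records(self, X) -> list:
        """Per-class coverage scores (#ID-Class) for each record."""
        self._check_fitted()
        frame = self.transform(X)
        kb = self.knowledge_base_
        pc = pat_mod.PatternCounts(
            cp_totals=kb.data_space.cp_totals, record_counts=frame,
        )
        class_map = self._scoring_class_map()
        return score_mod.score_all(pc, class_map, classes=self.classes_)

    def predict(self, X) -> np.ndarray:
        """Unsupervised cluster label per record (class-named; sentinel
        values mark ties and uncovered records)."""
        scores = self.score_records(X)
        return np.asarray([score_mod.assign_cluster(s) for s in scores],
                          dtype=object)

    def fit_predict(self, X, y):
        return self.fit(X, y).predict(X)

    def detect(self, X, y) -> tuple[list, dict]:
        """Triage records against their original labels.

        Returns (list of ErrorReport, summary counts).
        """
        self._check_fitted()
        X = _as_frame(X)
        labels = pd.Series(np.asarray(y, dtype=object), index=X.index)
        scores = self.score_records(X)
        th = self.thresholds or Thresholds()
        return _detect_all(scores, labels, th)

    def clean(self, X, y) -> tuple[CategoricalDataset, list]:
        """Remove triaged abnormal records; returns (dataset, removed IDs)."""
        reports, _ = self.detect(X, y)
        dataset = self._dataset(X, y)
        return _clean_dataset(dataset, reports)

    def score(self, X, y) -> float:
        """Clustering balanced accuracy of ``predict(X)`` against ``y``."""
        assigned = self.predict(X)
        return score_mod.evaluate_clustering(
            assigned, np.asarray(y, dtype=object),
            positive_class=self.positive_class,
        )["balanced_accuracy"]
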