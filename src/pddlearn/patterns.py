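"""Comprehensive pattern growth within DSUs and per-record counting.

A comprehensive pattern is a set of two or more attribute values drawn
from one DSU's summarized pattern (at most one value per attribute) such
that (a) the records containing every value of the set number at least
``min_support``, and (b) every value in the set is significantly
associated (|SR| >= threshold) with at least one other value of the set.
Enumeration is exhaustive up to ``max_order`` and deterministically
ordered (lexicographic on AV positions).

Support feasibility is anti-monotone, so candidates grow level-wise by
adding AVs with larger positions; the connectivity test is applied at
emission (it is not monotone, so pruning on it would lose valid sets).

Label AVs never enter pattern AV sets: counting patterns that contain
the class label would leak the label into the coverage scores.  The
label AV contributes only to the DSU's class association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretize import CategoricalDataset
from .disentangle import DSU
from .sr_matrix import SRMatrix, indicator_matrix

__all__ = ["ComprehensivePattern", "PatternCounts", "grow_patterns",
           "count_patterns", "default_min_support"]


def default_min_support(n_records: int) -> int:
    """max(5, 0.5% of N) — keeps growth at desk scale."""
    return max(5, int(round(0.005 * n_records)))


@dataclass
class ComprehensivePattern:
    dsu_code: tuple
    avs: tuple                    # AV positions, ascending
    av_pairs: tuple               # matching (attribute, category) pairs
    support: frozenset            # covering record IDs
    significance: float           # mean |SR| over significant member pairs


@dataclass
class PatternCounts:
    """#CP per DSU and the records x DSUs possession-count matrix."""

    cp_totals: dict                       # code -> #CP-DSU
    record_counts: pd.DataFrame           # index: record IDs, columns: code_str

    def count(self, record_id, code: tuple) -> int:
        return int(self.record_counts.at[record_id, _code_str(code)])


def _code_str(code: tuple) -> str:
    return ".".join(str(c) for c in code)


def _is_connected(avs: tuple, sig: np.ndarray) -> bool:
    for a in avs:
        if not any(sig[a, b] for b in avs if b != a):
            return False
    return True


def grow_patterns(
    dsu: DSU,
    dataset: CategoricalDataset,
    sr: SRMatrix,
    min_support: int | None = None,
    max_order: int = 5,
    threshold: float = 1.96,
    X: np.ndarray | None = None,
) -> list[ComprehensivePattern]:
    """Enumerate the DSU's comprehensive patterns.

    ``X`` may carry a precomputed indicator matrix for the dataset to
    avoid rebuilding it per DSU.
    """
    if min_support is None:
        min_support = default_min_support(dataset.n_records)
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if X is None:
        X = indicator_matrix(dataset.data, sr.index)
    label_attr = dataset.label_attribute
    cand = sorted(i for i in dsu.members if sr.index.avs[i][0] != label_attr)
    if len(cand) < 2:
        return []
    sig = np.abs(sr.residuals) >= threshold
    sig[sr.structural_zero] = False
    attr_of = {i: sr.index.avs[i][0] for i in cand}
    record_ids = np.asarray(dataset.record_ids, dtype=object)

    patterns: list[ComprehensivePattern] = []
    # frontier of support-feasible, attribute-distinct AV sets
    frontier: list[tuple[tuple, np.ndarray]] = []
    for pos, i in enumerate(cand):
        mask = X[:, i]
        if mask.sum() >= min_support:
            frontier.append(((i,), mask))

    order = 1
    while frontier and order < max_order:
        order += 1
        nxt = []
        for avs, mask in frontier:
            last = avs[-1]
            used = {attr_of[a] for a in avs}
            for j in cand:
                if j <= last or attr_of[j] in used:
                    continue
                m2 = mask & X[:, j]
                supp = int(m2.sum())
                if supp < min_support:
                    continue
                new = avs + (j,)
                # anti-monotone sanity: supersets never gain support
                assert supp <= mask.sum()
                nxt.append((new, m2))
                if _is_connected(new, sig):
                    pair_srs = [
                        abs(sr.residuals[a, b])
                        for ai, a in enumerate(new)
                        for b in new[ai + 1:]
                        if sig[a, b]
                    ]
                    patterns.append(
                        ComprehensivePattern(
                            dsu_code=dsu.code,
                            avs=new,
                            av_pairs=tuple(sr.index.avs[a] for a in new),
                            support=frozenset(record_ids[m2]),
                            significance=float(np.mean(pair_srs)),
                        )
                    )
        frontier = nxt
    patterns.sort(key=lambda p: p.avs)
    return patterns


def count_patterns(
    patterns_by_dsu: dict,
    dataset: CategoricalDataset,
    sr: SRMatrix,
    X: np.ndarray | None = None,
) -> PatternCounts:
    """#ID-DSU by subset containment of each pattern in each record.

    ``patterns_by_dsu`` maps DSU code -> list of patterns (possibly
    empty).  Works for any dataset sharing the fitted AV index, so new
    records can be counted against a fitted knowledge base.
    """
    if X is None:
        X = indicator_matrix(dataset.data, sr.index)
    codes = sorted(patterns_by_dsu.keys())
    counts = np.zeros((dataset.n_records, len(codes)), dtype=np.int64)
    totals = {}
    for j, code in enumerate(codes):
        plist = patterns_by_dsu[code]
        totals[code] = len(plist)
        for p in plist:
            counts[:, j] += X[:, list(p.avs)].all(axis=1)
    frame = pd.DataFrame(
        counts, index=dataset.record_ids, columns=[_code_str(c) for c in codes]
    )
    return PatternCounts(cp_totals=totals, record_counts=frame)
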