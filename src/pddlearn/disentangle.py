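"""Disentangle the SR-matrix into class-associated attribute-value units.

The SR-matrix is decomposed with an eigendecomposition (PCA of the
symmetric association matrix).  Each principal component contributes a
rank-one reconstructed SR-matrix, RSR_k = lambda_k v_k v_k^T, the unique
additive per-component decomposition of a symmetric matrix.  A component
is retained when some |RSR_k| entry (outside the structural zeros)
reaches the significance threshold (default 1.96).

On a retained component, AVs split into the two extremal groups of the
projection axis — an AV joins the group matching the sign of its loading
if it has at least one significant RSR partner; AVs with none sit near
the origin and are set aside.  Each group is then subdivided by
agglomerative clustering on entity overlap (Jaccard similarity of the
record sets each AV covers), yielding Disentangled Statistical Units
(DSUs) coded [#PC, #Group, #SubGroup].  A DSU carries a class
association when a label AV is among its members, or when the covered
entities show a clear majority class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .discretize import CategoricalDataset
from .sr_matrix import SRMatrix, indicator_matrix

__all__ = ["PCDecomposition", "AVGroup", "DSU", "decompose",
           "extract_av_groups", "subdivide", "assign_class", "disentangle",
           "refine_entities"]

_EIG_NOISE = 1e-10


@dataclass
class PCDecomposition:
    eigenvalues: np.ndarray      # ordered by descending |eigenvalue|
    eigenvectors: np.ndarray     # columns aligned with eigenvalues
    retained: np.ndarray         # bool per component
    threshold: float
    structural_zero: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def rsr(self, k: int) -> np.ndarray:
        """Rank-one reconstructed SR-matrix of component ``k``."""
        v = self.eigenvectors[:, k]
        return self.eigenvalues[k] * np.outer(v, v)

    @property
    def rsr_matrices(self) -> list[np.ndarray]:
        return [self.rsr(k) for k in range(self.n_components)]

    def reconstruction(self) -> np.ndarray:
        v = self.eigenvectors
        return (v * self.eigenvalues) @ v.T


@dataclass
class AVGroup:
    pc_id: int                    # 1-based component rank
    polarity: str                 # "+" or "-"
    members: list[int]            # AV positions


@dataclass
class DSU:
    """Disentangled Statistical Unit: one AV subgroup and its entities."""

    code: tuple                   # (#PC, #Group, #SubGroup), all 1-based
    members: list[int]            # AV positions in the SR index
    summarized_pattern: list = field(default_factory=list)  # (attr, cat) pairs
    entities: frozenset = frozenset()
    class_assoc: str | None = None

    @property
    def code_str(self) -> str:
        return ".".join(str(c) for c in self.code)


def decompose(sr: SRMatrix, threshold: float = 1.96) -> PCDecomposition:
    """Eigendecompose the SR-matrix and flag significant components."""
    r = sr.residuals
    if not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("SR-matrix must be symmetric")
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    order = np.argsort(-np.abs(w), kind="stable")
    w, v = w[order], v[:, order]
    # canonical sign: largest-|loading| entry positive
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    scale = np.abs(w).max(initial=0.0)
    keep = np.abs(w) > _EIG_NOISE * max(scale, 1.0)
    w, v = w[keep], v[:, keep]
    retained = np.zeros(w.size, dtype=bool)
    for k in range(w.size):
        rsr = np.abs(w[k] * np.outer(v[:, k], v[:, k]))
        rsr[sr.structural_zero] = 0.0
        retained[k] = rsr.max(initial=0.0) >= threshold
    return PCDecomposition(
        eigenvalues=w,
        eigenvectors=v,
        retained=retained,
        threshold=threshold,
        structural_zero=sr.structural_zero.copy(),
    )


def extract_av_groups(
    decomp: PCDecomposition, k: int, threshold: float | None = None
) -> tuple[AVGroup, AVGroup, list[int]]:
    """Split component ``k``'s AVs into the two extremal groups.

    Returns (positive group, negative group, insignificant AVs).  An AV
    is significant when it has at least one partner with |RSR| >= the
    threshold; otherwise it projects near the origin.
    """
    if threshold is None:
        threshold = decomp.threshold
    rsr = np.abs(decomp.rsr(k))
    rsr[decomp.structural_zero] = 0.0
    has_partner = (rsr >= threshold).any(axis=1)
    loading = decomp.eigenvectors[:, k]
    pos, neg, insig = [], [], []
    for i in range(loading.size):
        if not has_partner[i]:
            insig.append(i)
        elif loading[i] >= 0:
            pos.append(i)
        else:
            neg.append(i)
    return (
        AVGroup(pc_id=k + 1, polarity="+", members=pos),
        AVGroup(pc_id=k + 1, polarity="-", members=neg),
        insig,
    )


def _jaccard_distance(X: np.ndarray, members: list[int]) -> np.ndarray:
    sub = X[:, members].astype(np.int64)
    inter = sub.T @ sub
    sizes = sub.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    d = 1.0 - jac
    np.fill_diagonal(d, 0.0)
    return d


def subdivide(
    group: AVGroup,
    X: np.ndarray,
    method: str = "average",
    cut_distance: float = 0.5,
) -> list[list[int]]:
    """Cluster a group's AVs by entity overlap into DSU member lists.

    ``X`` is the boolean records x AVs indicator matrix.  Distance is
    1 - Jaccard overlap of the covering record sets; the average-linkage
    tree is cut at ``cut_distance``.  Clusters are ordered by their
    smallest AV position so subgroup numbering is deterministic.
    """
    m = group.members
    if not m:
        return []
    if len(m) == 1:
        return [list(m)]
    d = _jaccard_distance(X, m)
    z = linkage(squareform(d, checks=False), method=method)
    flat = fcluster(z, t=cut_distance, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for av, c in zip(m, flat):
        clusters.setdefault(int(c), []).append(av)
    return sorted((sorted(c) for c in clusters.values()), key=lambda c: c[0])


def assign_class(
    members: list[int],
    entities: frozenset,
    sr: SRMatrix,
    dataset: CategoricalDataset,
    margin: float = 0.1,
) -> str | None:
    """Class association of one DSU.

    A label AV among the members decides directly.  Otherwise the class
    most enriched among the covered entities decides, provided its share
    exceeds its global prevalence by more than ``margin`` — an absolute
    majority would be blind to minority classes in imbalanced data,
    where a unit can be strongly class-specific while the majority class
    still dominates its cover.  Weak enrichment gives no association
    ("rare patterns not associated with any class").
    """
    label_attr = dataset.label_attribute
    label_avs = [sr.index.avs[i][1] for i in members
                 if sr.index.avs[i][0] == label_attr]
    if len(label_avs) == 1:
        return label_avs[0]
    if len(label_avs) > 1:
        return None  # contradictory label membership
    if not entities:
        return None
    prevalence = dataset.labels().value_counts(normalize=True)
    shares = dataset.labels().loc[list(entities)].value_counts(normalize=True)
    lift = (shares - prevalence.reindex(shares.index)).sort_values(
        ascending=False, kind="stable"
    )
    if len(lift) == 0:
        return None
    if len(lift) > 1 and lift.iloc[0] == lift.iloc[1]:
        return None  # tied enrichment
    if lift.iloc[0] > margin:
        return str(lift.index[0])
    return None


def _dsu_entities(
    members: list[int], X: np.ndarray, record_ids: list, sr: SRMatrix,
    label_attr: str,
) -> frozenset:
    feature = [i for i in members if sr.index.avs[i][0] != label_attr]
    cols = feature if feature else list(members)
    mask = X[:, cols].any(axis=1)
    return frozenset(rid for rid, hit in zip(record_ids, mask) if hit)


def disentangle(
    sr: SRMatrix,
    dataset: CategoricalDataset,
    threshold: float = 1.96,
    linkage_method: str = "average",
    cut_distance: float = 0.8,
    class_margin: float = 0.1,
    positive_class: str | None = None,
) -> tuple[list[DSU], PCDecomposition]:
    """Full disentanglement: decompose, group, subdivide, classify.

    Group numbering within a retained component: the group associated
    with ``positive_class`` (when given and unambiguous) is #Group 1;
    otherwise the "+" polarity group is #Group 1.
    """
    decomp = decompose(sr, threshold=threshold)
    X = indicator_matrix(dataset.data, sr.index)
    record_ids = dataset.record_ids
    label_attr = dataset.label_attribute
    dsus: list[DSU] = []
    pc_rank = 0
    for k in np.flatnonzero(decomp.retained):
        pc_rank += 1
        gpos, gneg, _ = extract_av_groups(decomp, int(k), threshold)
        ordered = [gpos, gneg]
        if positive_class is not None:
            pos_av = (label_attr, positive_class)
            if pos_av in sr.index.lookup:
                j = sr.index.lookup[pos_av]
                if j in gneg.members and j not in gpos.members:
                    ordered = [gneg, gpos]
        for gnum, grp in enumerate(ordered, start=1):
            for snum, members in enumerate(
                subdivide(grp, X, method=linkage_method, cut_distance=cut_distance),
                start=1,
            ):
                ents = _dsu_entities(members, X, record_ids, sr, label_attr)
                cls = assign_class(members, ents, sr, dataset, margin=class_margin)
                dsus.append(
                    DSU(
                        code=(pc_rank, gnum, snum),
                        members=members,
                        summarized_pattern=[sr.index.avs[i] for i in members],
                        entities=ents,
                        class_assoc=cls,
                    )
                )
    return dsus, decomp


def refine_entities(
    dsus: list,
    counts,
    dataset: CategoricalDataset,
    sr: SRMatrix,
    margin: float = 0.1,
) -> None:
    """Tighten DSU entities to pattern possession and revisit classes.

    A record counts as covered by a DSU once it possesses at least one
    of its comprehensive patterns (a zero possession count means "not
    covered"), which is sharper than merely holding one member AV.
    After pattern growth this replaces each patterned DSU's entity set
    with its pattern cover and re-derives the class association from the
    enriched cover; label-AV membership still decides first.  DSUs
    without patterns keep their AV-cover entities.  Modifies in place.
    """
    frame = counts.record_counts
    for d in dsus:
        col = d.code_str
        if col not in frame.columns or counts.cp_totals.get(tuple(d.code), 0) == 0:
            continue
        covered = frame.index[frame[col] > 0]
        d.entities = frozenset(covered)
        d.class_assoc = assign_class(
            d.members, d.entities, sr, dataset, margin=margin
        )
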