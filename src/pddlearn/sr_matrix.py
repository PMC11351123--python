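"""Adjusted standardized residual matrix over attribute-value pairs.

For every pair of attribute values (AVs) the association strength is the
Haberman adjusted standardized residual

    SR(a, b) = (Occ(a, b) - Exp(a, b))
               / sqrt(Exp(a, b) * (1 - Occ(a)/N) * (1 - Occ(b)/N))

where ``Occ`` counts records holding an AV (or both AVs), ``Exp(a, b) =
Occ(a) * Occ(b) / N`` is the expected co-occurrence under independence,
and N is the record count.  Under independence SR is asymptotically
standard normal, so |SR| >= 1.96 marks an association significant at the
~95% level.

Pairs of values of the same attribute cannot co-occur in a record; those
entries (and the diagonal) are structural zeros, masked rather than
computed.  Degenerate denominators (Exp = 0, or a marginal equal to N)
yield SR = 0 and are flagged, never infinity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import CategoricalDataset

__all__ = ["AVIndex", "SRMatrix", "count_marginals", "adjusted_residual",
           "build_sr_matrix", "indicator_matrix"]


@dataclass(frozen=True)
class AVIndex:
    """Ordered registry of (attribute, category) pairs."""

    avs: tuple  # tuple of (attribute, category)

    @property
    def lookup(self) -> dict:
        return {av: i for i, av in enumerate(self.avs)}

    @property
    def attributes(self) -> np.ndarray:
        return np.array([a for a, _ in self.avs], dtype=object)

    def __len__(self) -> int:
        return len(self.avs)

    def position(self, attribute: str, category: str) -> int:
        return self.lookup[(attribute, category)]

    def names(self) -> list[str]:
        return [f"{a}={c}" for a, c in self.avs]

    @classmethod
    def from_dataset(cls, dataset: CategoricalDataset, include_label: bool = True):
        avs = []
        for attr in dataset.attributes:
            if attr == dataset.label_attribute and not include_label:
                continue
            for cat in dataset.categories(attr):
                avs.append((attr, cat))
        return cls(avs=tuple(avs))


def indicator_matrix(data: pd.DataFrame, index: AVIndex) -> np.ndarray:
    """Boolean records x AVs membership matrix.

    Categories absent from ``index`` (unseen at fit time) simply produce
    all-False columns for their attribute.
    """
    n = data.shape[0]
    X = np.zeros((n, len(index)), dtype=bool)
    lut = index.lookup
    for attr in data.columns:
        col = data[attr].astype(str).to_numpy()
        for j, (a, c) in enumerate(index.avs):
            if a == attr:
                X[:, j] = col == c
    return X


def count_marginals(
    dataset: CategoricalDataset, include_label: bool = True
) -> tuple[np.ndarray, np.ndarray, int, AVIndex]:
    """Exact occurrence and co-occurrence counts for every AV pair."""
    if dataset.n_records == 0:
        raise ValueError("empty dataset")
    index = AVIndex.from_dataset(dataset, include_label=include_label)
    X = indicator_matrix(dataset.data, index).astype(np.int64)
    cooc = X.T @ X
    occ = np.diag(cooc).copy()
    return occ, cooc, dataset.n_records, index


def adjusted_residual(
    occ_pair: float, exp_pair: float, occ_a: float, occ_b: float, n: int
) -> tuple[float, bool]:
    """One adjusted standardized residual; returns (value, degenerate flag)."""
    if n <= 0:
        raise ValueError("N must be positive")
    var = exp_pair * (1.0 - occ_a / n) * (1.0 - occ_b / n)
    if var <= 0.0:
        return 0.0, True
    return (occ_pair - exp_pair) / np.sqrt(var), False


@dataclass
class SRMatrix:
    """Symmetric adjusted-residual matrix with its producing counts.

    Attributes
    ----------
    index : AVIndex
    residuals : (m, m) float array, symmetric, zero on structural cells
    occurrences : (m,) int array of Occ(AV)
    co_occurrences : (m, m) int array of Occ(AV1, AV2)
    n_records : int
    structural_zero : (m, m) bool mask — diagonal and within-attribute
        cells, excluded from any significance reasoning
    degenerate : (m, m) bool mask of cells whose denominator vanished
    """

    index: AVIndex
    residuals: np.ndarray
    occurrences: np.ndarray
    co_occurrences: np.ndarray
    n_records: int
    structural_zero: np.ndarray
    degenerate: np.ndarray

    @property
    def n_avs(self) -> int:
        return len(self.index)

    def to_frame(self) -> pd.DataFrame:
        names = self.index.names()
        return pd.DataFrame(self.residuals, index=names, columns=names)

    def save(self, tsv_path, sidecar_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "n_records": self.n_records,
                        "occurrences": {
                            name: int(o)
                            for name, o in zip(self.index.names(), self.occurrences)
                        },
                    },
                    fh,
                    indent=2,
                )


def build_sr_matrix(
    dataset: CategoricalDataset, include_label: bool = True
) -> SRMatrix:
    """Build the full symmetric SR-matrix for a categorical dataset.

    The label attribute's AVs are included by default so that
    disentangled units can carry a direct class association; pass
    ``include_label=False`` for a fully label-blind run.
    """
    occ, cooc, n, index = count_marginals(dataset, include_label=include_label)
    occf = occ.astype(float)
    exp = np.outer(occf, occf) / n
    var = exp * np.outer(1.0 - occf / n, 1.0 - occf / n)
    attrs = index.attributes
    structural = attrs[:, None] == attrs[None, :]  # includes the diagonal
    degenerate = (var <= 0.0) & ~structural
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(var > 0.0, (cooc - exp) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    sr[structural] = 0.0
    sr[degenerate] = 0.0
    sr = (sr + sr.T) / 2.0  # exact symmetry against float noise
    return SRMatrix(
        index=index,
        residuals=sr,
        occurrences=occ,
        co_occurrences=cooc,
        n_records=n,
        structural_zero=structural,
        degenerate=degenerate,
    )
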