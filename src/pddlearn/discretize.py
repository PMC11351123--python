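"""Discretization of numeric attributes into categorical attribute values.

Pattern discovery over tabular data operates on categorical attribute
values (AVs).  Numeric clinical measurements are first mapped to
event-based categories, either through clinician-defined bins (e.g. the
Glasgow Coma Scale bands Severe/Moderate/Mild) or through equal-frequency
binning, which sorts the values and splits them into bins holding an
equal number of records.

Interval convention for clinical bins: with internal cut points
``e1 < e2 < ...`` and labels ``L0, L1, ..., Lk``, a value ``v`` maps to
``L0`` if ``v < e1``, to ``Li`` (``1 <= i < k``) if ``v <= e_{i+1}``, and
to ``Lk`` otherwise.  This makes the first range open above and every
later range closed above, so a shared printed boundary (a systolic
pressure of exactly 90 in "<90 / 90-120 / >120") belongs to the range
whose closed printed interval contains it.

Missing numeric values map to an explicit ``"missing"`` category; rows
are never dropped or imputed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "missing"

__all__ = [
    "MISSING",
    "BinningScheme",
    "CategoricalDataset",
    "discretize_clinical",
    "discretize_equal_frequency",
    "apply_schemes",
    "clinical_scheme",
    "save_schemes",
    "load_schemes",
]


@dataclass(frozen=True)
class BinningScheme:
    """How one numeric attribute becomes categorical.

    Parameters
    ----------
    attribute : str
        Column name the scheme applies to.
    kind : {"clinical", "equal_frequency", "passthrough"}
    edges : tuple of float
        Internal cut points, strictly increasing.  For ``clinical``
        schemes they are fixed by the user; for ``equal_frequency``
        schemes they are the realized cut values after fitting.
    labels : tuple of str
        Category names, one per interval (``len(edges) + 1``).
    n_bins : int
        Requested bin count for ``equal_frequency`` (>= 2).
    unit : str
        Measurement unit, recorded for provenance only.
    lower_bound, upper_bound : float or None
        Optional closed admissible range; values outside are rejected.
        ``None`` means the corresponding side is open-ended.
    """

    attribute: str
    kind: str
    edges: tuple = ()
    labels: tuple = ()
    n_bins: int = 3
    unit: str = ""
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("clinical", "equal_frequency", "passthrough"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.kind == "equal_frequency":
            # realized quantile cuts may coincide under heavy ties
            if any(b > a for b, a in zip(edges, edges[1:])):
                raise ValueError(f"{self.attribute}: edges must be non-decreasing")
        elif any(b >= a for b, a in zip(edges, edges[1:])):
            raise ValueError(f"{self.attribute}: edges must be strictly increasing")
        if self.kind == "clinical":
            if len(self.labels) != len(edges) + 1:
                raise ValueError(
                    f"{self.attribute}: need {len(edges) + 1} labels for "
                    f"{len(edges)} cut points, got {len(self.labels)}"
                )
        if self.kind == "equal_frequency" and self.n_bins < 2:
            raise ValueError(f"{self.attribute}: equal-frequency n_bins must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "BinningScheme":
        return cls(**dict(d))


def clinical_scheme(
    attribute: str,
    edges: Sequence[float],
    labels: Sequence[str],
    unit: str = "",
    lower_bound: float | None = None,
    upper_bound: float | None = None,
) -> BinningScheme:
    """Convenience constructor for a clinician-defined scheme."""
    return BinningScheme(
        attribute=attribute,
        kind="clinical",
        edges=tuple(edges),
        labels=tuple(labels),
        unit=unit,
        lower_bound=lower_bound,
        upper_bound=upper_bound,
    )


def _clinical_bin_index(v: float, edges: Sequence[float]) -> int:
    # first interval open above, later intervals closed above
    if v < edges[0]:
        return 0
    for i, e in enumerate(edges[1:], start=1):
        if v <= e:
            return i
    return len(edges)


def discretize_clinical(values: pd.Series, scheme: BinningScheme) -> pd.Series:
    """Map a numeric series onto clinician-defined category labels.

    Values already equal to one of the scheme's labels pass through
    unchanged (idempotence on binned data).  Missing values map to
    :data:`MISSING`.  A value outside a declared closed bound is
    rejected with the attribute and value named.
    """
    if scheme.kind != "clinical":
        raise ValueError(f"scheme for {scheme.attribute!r} is not clinical")
    label_set = set(scheme.labels) | {MISSING}
    out = []
    for v in values:
        if isinstance(v, str) and v in label_set:
            out.append(v)  # already binned
            continue
        if pd.isna(v):
            out.append(MISSING)
            continue
        v = float(v)
        if scheme.lower_bound is not None and v < scheme.lower_bound:
            raise ValueError(
                f"{scheme.attribute}: value {v} below admissible bound "
                f"{scheme.lower_bound}"
            )
        if scheme.upper_bound is not None and v > scheme.upper_bound:
            raise ValueError(
                f"{scheme.attribute}: value {v} above admissible bound "
                f"{scheme.upper_bound}"
            )
        out.append(scheme.labels[_clinical_bin_index(v, scheme.edges)])
    return pd.Series(out, index=values.index, name=values.name, dtype=object)


def discretize_equal_frequency(
    values: pd.Series,
    n_bins: int = 3,
    labels: Sequence[str] | None = None,
    attribute: str | None = None,
) -> tuple[pd.Series, BinningScheme]:
    """Equal-frequency (quantile) binning.

    Non-missing values are sorted ascending and split into ``n_bins``
    intervals each holding an equal number of records.  The realized cut
    value for bin boundary ``i`` is the largest member of the ideal
    ``i``-th bin; every value equal to a cut point falls in the lower
    bin, so ties are never split across bins and the result does not
    depend on record order.  Occupancy imbalance caused by ties is
    reported through the realized scheme, not corrected.

    Returns the categorical series and the realized
    :class:`BinningScheme` (with the fitted ``edges``).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    name = attribute or values.name or "value"
    numeric = pd.to_numeric(values, errors="raise")
    clean = numeric.dropna().to_numpy(dtype=float)
    if np.unique(clean).size < n_bins:
        raise ValueError(
            f"{name}: needs at least {n_bins} distinct values for "
            f"{n_bins} equal-frequency bins"
        )
    a = np.sort(clean)
    n = a.size
    # cut i = last member of the ideal i-th bin
    cut_idx = [int(np.ceil(i * n / n_bins)) - 1 for i in range(1, n_bins)]
    cuts = tuple(float(a[i]) for i in cut_idx)
    if labels is None:
        labels = tuple(f"bin{i + 1}" for i in range(n_bins))
    else:
        labels = tuple(labels)
        if len(labels) != n_bins:
            raise ValueError(f"{name}: need {n_bins} labels, got {len(labels)}")
    scheme = BinningScheme(
        attribute=name, kind="equal_frequency", edges=cuts, labels=labels,
        n_bins=n_bins,
    )
    out = numeric.map(
        lambda v: MISSING if pd.isna(v)
        else labels[int(np.sum(np.asarray(cuts) < float(v)))]
    )
    return out.astype(object), scheme


def _apply_fitted_equal_frequency(values: pd.Series, scheme: BinningScheme) -> pd.Series:
    cuts = np.asarray(scheme.edges, dtype=float)
    labels = scheme.labels
    numeric = pd.to_numeric(values, errors="raise")
    out = numeric.map(
        lambda v: MISSING if pd.isna(v)
        else labels[int(np.sum(cuts < float(v)))]
    )
    return out.astype(object)


@dataclass
class CategoricalDataset:
    """Records x attributes table of categorical values plus a label column.

    ``data`` holds one row per record (index = unique record IDs) and one
    column per attribute, all values categorical (strings).  The label
    attribute is one of the columns; its categories are the classes.
    """

    data: pd.DataFrame
    label_attribute: str
    schemes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise ValueError("dataset has no records")
        if not self.data.index.is_unique:
            raise ValueError("record IDs must be unique")
        if self.label_attribute not in self.data.columns:
            raise ValueError(f"label attribute {self.label_attribute!r} not in table")
        self.data = self.data.astype(str)

    @property
    def record_ids(self) -> list:
        return list(self.data.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def feature_attributes(self) -> list[str]:
        return [c for c in self.data.columns if c != self.label_attribute]

    @property
    def classes(self) -> list[str]:
        return sorted(self.data[self.label_attribute].unique())

    @property
    def n_records(self) -> int:
        return int(self.data.shape[0])

    def labels(self) -> pd.Series:
        return self.data[self.label_attribute]

    def categories(self, attribute: str) -> list[str]:
        return sorted(self.data[attribute].unique())

    def drop_records(self, record_ids: Iterable) -> "CategoricalDataset":
        keep = self.data.drop(index=list(record_ids))
        return CategoricalDataset(keep, self.label_attribute, dict(self.schemes))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="record_id")

    @classmethod
    def from_csv(cls, path, label_attribute: str, id_column: str = "record_id"):
        df = pd.read_csv(path, dtype=str).set_index(id_column)
        return cls(df, label_attribute)


def apply_schemes(
    table: pd.DataFrame,
    schemes: Mapping[str, BinningScheme],
    label_attribute: str,
    default_n_bins: int = 3,
) -> CategoricalDataset:
    """Convert a mixed-type table to an all-categorical dataset.

    Columns with a clinical scheme are binned by it; other numeric
    columns get equal-frequency binning with ``default_n_bins`` bins
    unless an ``equal_frequency`` scheme is supplied (a fitted scheme —
    one with realized edges — is re-applied verbatim, which makes a
    persisted registry reproducible).  Non-numeric columns pass through
    as categories.  The realized scheme registry is stored on the
    returned dataset.
    """
    out = {}
    realized: dict[str, BinningScheme] = {}
    for col in table.columns:
        s = table[col]
        scheme = schemes.get(col)
        if scheme is not None and scheme.kind == "clinical":
            out[col] = discretize_clinical(s, scheme)
            realized[col] = scheme
        elif scheme is not None and scheme.kind == "passthrough":
            out[col] = s.astype(str)
            realized[col] = scheme
        elif scheme is not None and scheme.kind == "equal_frequency":
            if scheme.edges:  # already fitted: re-apply
                out[col] = _apply_fitted_equal_frequency(s, scheme)
                realized[col] = scheme
            else:
                out[col], realized[col] = discretize_equal_frequency(
                    s, scheme.n_bins, labels=scheme.labels or None, attribute=col
                )
        elif pd.api.types.is_numeric_dtype(s) and col != label_attribute:
            out[col], realized[col] = discretize_equal_frequency(
                s, default_n_bins, attribute=col
            )
        else:
            out[col] = s.astype(str)
            realized[col] = BinningScheme(attribute=col, kind="passthrough")
    df = pd.DataFrame(out, index=table.index)
    return CategoricalDataset(df, label_attribute, realized)


def save_schemes(schemes: Mapping[str, BinningScheme], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in schemes.items()}, fh, indent=2)


def load_schemes(path) -> dict[str, BinningScheme]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: BinningScheme.from_dict(v) for k, v in raw.items()}
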