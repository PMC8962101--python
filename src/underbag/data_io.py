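"""Loading, validation and cleaning of tabular clinical datasets.

A dataset is one row per subject: mixed continuous and binary-categorical
feature columns plus a binary label column, with 1 marking the case
(minority, positive) class and 0 the control (majority, negative) class.
Missing cells are tolerated at load time and removed row-wise by
:func:`drop_missing`; every downstream stage assumes a complete table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("underbag")

#: Cell values treated as missing when reading CSV (configurable per call).
DEFAULT_NA_VALUES: tuple[str, ...] = ("", "NA")

FEATURE_KINDS = ("continuous", "categorical")
FEATURE_GROUPS = ("blood_routine", "biochemical", "clotting", "other")


@dataclass(frozen=True)
class FeatureSpec:
    """Metadata for one feature column.

    Parameters
    ----------
    name
        Column name, unique within a dataset.
    kind
        ``"continuous"`` or ``"categorical"``. Categorical features are
        binary after encoding (0/1).
    group
        Optional clinical panel the feature belongs to (blood routine,
        biochemical, clotting, other). Informational only.
    mapping
        Optional explicit encoding for categorical string levels, e.g.
        ``{"yes": 1, "no": 0}``. Values must be 0 or 1.
    """

    name: str
    kind: str = "continuous"
    group: str | None = None
    mapping: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.group is not None and self.group not in FEATURE_GROUPS:
            raise ValueError(f"unknown feature group {self.group!r}")
        if self.mapping is not None and not set(self.mapping.values()) <= {0, 1}:
            raise ValueError("categorical mapping values must be 0 or 1")


@dataclass
class ClinicalTable:
    """An n x p feature matrix with per-feature metadata and binary labels.

    ``y == 1`` marks the positive / minority class P, ``y == 0`` the
    negative / majority class N.
    """

    features: list[FeatureSpec]
    X: np.ndarray
    y: np.ndarray
    label_column: str = "label"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[1] != len(self.features):
            raise ValueError(
                f"X has {self.X.shape[1]} columns but {len(self.features)} "
                "feature specs were given"
            )
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        labels = set(np.unique(self.y[~pd.isna(self.y)]).tolist())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, found {sorted(labels)}")
        self.y = self.y.astype(int)
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError("both classes must be present (|P| >= 1 and |N| >= 1)")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if self.n_pos > self.n_neg:
            warnings.warn(
                "class 1 is larger than class 0; the method assumes the "
                "positive class is the minority",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.y == 0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        for spec in self.features:
            if spec.kind == "categorical":
                col = df[spec.name]
                intlike = col.dropna() == col.dropna().astype(int)
                if bool(intlike.all()) and not col.isna().any():
                    df[spec.name] = col.astype(int)
        df[self.label_column] = self.y
        return df

    def subset(self, rows: np.ndarray) -> "ClinicalTable":
        """Row subset (boolean mask or integer index array)."""
        return replace(self, X=self.X[rows], y=self.y[rows])


@dataclass(frozen=True)
class CleanReport:
    """Accounting of row-wise missing-data removal."""

    n_input: int
    n_dropped_missing: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_dropped_missing + self.n_retained:
            raise ValueError("CleanReport counts are inconsistent")


def _infer_kind(col: pd.Series) -> str:
    values = set(col.dropna().unique().tolist())
    if values <= {0, 1, 0.0, 1.0}:
        return "categorical"
    return "continuous"


def load_table(
    path,
    label_column: str,
    feature_specs: list[FeatureSpec] | None = None,
    na_values: tuple[str, ...] = DEFAULT_NA_VALUES,
) -> ClinicalTable:
    """Read a CSV file (header row, RFC-4180) into a :class:`ClinicalTable`.

    Feature kinds are inferred when no specs are given: a column whose
    observed values lie in {0, 1} is categorical, any other numeric column
    is continuous. Non-numeric columns require a spec with an explicit
    ``mapping``; categorical columns with more than two levels are
    rejected. Row order is preserved; missing cells stay as NaN until
    :func:`drop_missing`.
    """
    df = pd.read_csv(
        path, dtype=object, keep_default_na=False, na_values=list(na_values)
    )
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")

    y_raw = pd.to_numeric(df[label_column], errors="coerce")
    if y_raw.isna().any():
        row = int(y_raw.index[y_raw.isna()][0])
        raise ValueError(
            f"unparsable label at row {row} in column {label_column!r}"
        )
    if not set(y_raw.unique().tolist()) <= {0, 1}:
        raise ValueError(
            f"label column {label_column!r} must be binary 0/1, "
            f"found values {sorted(set(y_raw.unique().tolist()))}"
        )

    spec_by_name = {s.name: s for s in feature_specs} if feature_specs else {}
    feature_cols = [c for c in df.columns if c != label_column]
    specs: list[FeatureSpec] = []
    columns: list[np.ndarray] = []
    for name in feature_cols:
        raw = df[name]
        spec = spec_by_name.get(name)
        if spec is not None and spec.mapping is not None:
            unmapped = set(raw.dropna().unique()) - set(spec.mapping)
            if unmapped:
                row = int(raw.index[raw.isin(unmapped)][0])
                raise ValueError(
                    f"unparsable cell at row {row}, column {name!r}: "
                    f"value {raw.iloc[row]!r} not in mapping"
                )
            col = raw.map(spec.mapping).astype(float)
        else:
            col = pd.to_numeric(raw, errors="coerce")
            bad = col.isna() & raw.notna()
            if bad.any():
                row = int(bad.index[bad][0])
                raise ValueError(
                    f"unparsable cell at row {row}, column {name!r}: "
                    f"{raw.iloc[row]!r}"
                )
        kind = spec.kind if spec is not None else _infer_kind(col)
        if kind == "categorical":
            levels = set(col.dropna().unique().tolist())
            if not levels <= {0.0, 1.0}:
                raise ValueError(
                    f"categorical column {name!r} has more than two levels "
                    f"({sorted(levels)}); only binary categoricals are supported"
                )
        if spec is None:
            spec = FeatureSpec(name=name, kind=kind)
        specs.append(spec)
        columns.append(col.to_numpy(dtype=float))

    X = np.column_stack(columns) if columns else np.empty((len(df), 0))
    table = ClinicalTable(
        features=specs,
        X=X,
        y=y_raw.to_numpy(dtype=int),
        label_column=label_column,
    )
    logger.info(
        "loaded %d rows x %d features from %s (|P|=%d, |N|=%d)",
        table.n_samples, table.n_features, path, table.n_pos, table.n_neg,
    )
    return table


def write_table(table: ClinicalTable, path) -> None:
    """Write a table back to CSV so that :func:`load_table` round-trips it."""
    df = table.to_frame()
    df.to_csv(path, index=False)


def drop_missing(table: ClinicalTable) -> tuple[ClinicalTable, CleanReport]:
    """Remove every row with at least one missing cell.

    Returns the cleaned table and a :class:`CleanReport`; raises if no
    rows survive. Idempotent on clean tables.
    """
    keep = ~np.isnan(table.X).any(axis=1)
    n_input = table.n_samples
    n_retained = int(keep.sum())
    if n_retained == 0:
        raise ValueError("all rows contain missing data; empty dataset")
    report = CleanReport(
        n_input=n_input,
        n_dropped_missing=n_input - n_retained,
        n_retained=n_retained,
    )
    logger.info(
        "drop_missing: retained %d of %d rows (%d dropped)",
        report.n_retained, report.n_input, report.n_dropped_missing,
    )
    return table.subset(keep), report


def imbalance_ratio(table: ClinicalTable) -> float:
    """|N| / |P|, the majority-to-minority ratio (e.g. 65.35 reported as 1:65)."""
    if table.n_pos == 0:
        raise ValueError("no positive samples; imbalance ratio undefined")
    return table.n_neg / table.n_pos
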