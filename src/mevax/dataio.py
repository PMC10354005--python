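"""Tabular input and the four-step preprocessing chain.

Reads a samples x features table (CSV/TSV, one binary label column) and
applies, in order: nominal-to-numeric encoding, missing-value imputation,
per-feature normalization, and merging of duplicate-named feature columns.
The result is a clean numeric :class:`Dataset` ready for the evolutionary
run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

#: Cell values (case-insensitive) recognized as missing markers.
MISSING_MARKERS = {"", "na", "nan", "null"}


class ConfigurationError(ValueError):
    """User-supplied configuration is inconsistent with the data."""


class DataError(ValueError):
    """The data itself violates a requirement (e.g. a fully-missing column)."""


@dataclass
class RawTable:
    """A possibly-dirty table: numeric, nominal and missing cells coexist.

    ``values`` holds the feature columns (label column excluded); numeric
    columns have float dtype, nominal columns object dtype with ``NaN`` for
    missing cells.  ``labels`` is the raw binary outcome column.
    """

    values: pd.DataFrame
    labels: pd.Series
    label_column: str
    nominal_encodings: dict[str, dict[str, int]] = field(default_factory=dict)
    imputed_counts: dict[str, int] = field(default_factory=dict)
    normalization: dict | None = None

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    def validate(self) -> None:
        if self.values.shape[0] < 2:
            raise DataError("need at least 2 samples")
        if self.values.shape[1] < 1:
            raise DataError("need at least one feature column besides the label")
        classes = self.labels.dropna().unique()
        if len(classes) != 2:
            raise DataError(
                f"label column {self.label_column!r} must have exactly 2 classes, "
                f"found {len(classes)}"
            )


@dataclass
class Dataset:
    """Clean numeric matrix with binary labels.

    Invariants: ``X`` is finite, feature names are unique, ``y`` contains
    both classes.  ``positive_label`` records which original label value was
    mapped to 1 (the minority class; ties broken by sorted order).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    positive_label: object
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not np.all(np.isfinite(self.X)):
            raise DataError("Dataset.X contains non-finite values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("Dataset feature names must be unique")
        if set(np.unique(self.y)) != {0, 1}:
            raise DataError("Dataset.y must contain both classes 0 and 1")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(self.X.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.y) - self.y.sum())

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.X).tobytes())
        h.update(self.y.tobytes())
        h.update("\x00".join(self.feature_names).encode())
        return h.hexdigest()[:16]

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names, index=self.sample_ids)
        df[label_column] = self.y
        return df


def _coerce_column(col: pd.Series) -> pd.Series:
    """Type a raw column: numeric where fully parseable, else nominal object."""
    as_str = col.astype("string")
    stripped = as_str.str.strip()
    missing = col.isna() | stripped.str.lower().isin(MISSING_MARKERS)
    numeric = pd.to_numeric(stripped.where(~missing), errors="coerce")
    if (numeric.isna() == missing).all():
        return numeric.astype(float)
    out = stripped.astype(object).where(~missing, np.nan)
    return out


def load_table(path, label_column: str) -> RawTable:
    """Read a CSV/TSV file into a :class:`RawTable`.

    The delimiter is taken from the extension (``.tsv``/``.tab`` -> tab),
    falling back to whichever of tab/comma appears in the header line.
    Cells equal to any :data:`MISSING_MARKERS` entry are flagged missing.
    """
    path = str(path)
    if path.endswith((".tsv", ".tab", ".txt")):
        sep = "\t"
    else:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if ("\t" in header and "," not in header) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return table_from_frame(df, label_column)


def table_from_frame(df: pd.DataFrame, label_column: str) -> RawTable:
    """Build a :class:`RawTable` from an in-memory frame (cells may be mixed)."""
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found; columns are "
            f"{list(df.columns)[:10]}..."
        )
    labels = df[label_column].copy()
    if labels.dtype == object or pd.api.types.is_string_dtype(labels):
        lab_str = labels.astype("string").str.strip()
        labels = labels.where(~lab_str.str.lower().isin(MISSING_MARKERS), np.nan)
    values = df.drop(columns=[label_column]).apply(_coerce_column)
    raw = RawTable(values=values, labels=labels, label_column=label_column)
    raw.validate()
    return raw


def encode_nominal(raw: RawTable) -> RawTable:
    """Replace each nominal column by integer codes in sorted lexical order.

    ``["low", "high", "low"] -> [1, 0, 1]`` since ``high`` sorts before
    ``low``.  The code mapping is recorded in ``nominal_encodings`` for the
    preprocessing report.  Numeric columns pass through unchanged.
    """
    values = raw.values.copy()
    encodings = dict(raw.nominal_encodings)
    for j in range(values.shape[1]):  # positional: names may be duplicated
        col = values.iloc[:, j]
        if col.dtype == object:
            distinct = sorted(str(v) for v in col.dropna().unique())
            mapping = {v: i for i, v in enumerate(distinct)}
            encodings[str(values.columns[j])] = mapping
            values.isetitem(j, col.map(
                lambda v: mapping[str(v)] if not pd.isna(v) else np.nan
            ).astype(float))
    return RawTable(values=values, labels=raw.labels, label_column=raw.label_column,
                    nominal_encodings=encodings, imputed_counts=dict(raw.imputed_counts),
                    normalization=raw.normalization)


def _binary_labels(raw: RawTable) -> tuple[np.ndarray, object]:
    """Map the two label values to {0,1}: minority class -> 1 (ties: sorted order)."""
    lab = raw.labels
    counts = lab.value_counts()
    classes = sorted(counts.index, key=str)
    if counts[classes[0]] == counts[classes[1]]:
        positive = classes[1]
    else:
        positive = counts.idxmin()
    y = (lab == positive).astype(int).to_numpy()
    return y, positive


def impute_missing(raw: RawTable, strategy: str = "median") -> RawTable:
    """Fill missing cells.

    ``median`` (default): per-feature, per-class median where both classes
    have at least one observed value for that feature, otherwise the global
    feature median.  ``mean``: same scheme with means.  ``knn-<k>``:
    scikit-learn KNN imputation with k neighbours (class-blind).
    """
    values = raw.values
    mat = values.to_numpy(dtype=float)
    miss = np.isnan(mat)
    fully = miss.all(axis=0)
    if fully.any():
        bad = [str(values.columns[j]) for j in np.flatnonzero(fully)]
        raise DataError(f"fully-missing column(s): {bad}")
    counts = {str(values.columns[j]): int(miss[:, j].sum())
              for j in np.flatnonzero(miss.any(axis=0))}
    if not counts:
        out = values.copy()
    elif strategy.startswith("knn"):
        k = int(strategy.split("-")[1]) if "-" in strategy else 5
        imputer = KNNImputer(n_neighbors=k)
        out = pd.DataFrame(imputer.fit_transform(mat), columns=values.columns,
                           index=values.index)
    elif strategy in ("median", "mean"):
        stat = np.nanmedian if strategy == "median" else np.nanmean
        y, _ = _binary_labels(raw)
        filled = mat.copy()
        global_fill = stat(mat, axis=0)
        # class-conditional fill only for features observed in both classes
        observed_in_both = ~miss[y == 0].all(axis=0) & ~miss[y == 1].all(axis=0)
        for cls in (0, 1):
            rows = y == cls
            with warnings.catch_warnings():  # all-NaN class slices fall back anyway
                warnings.simplefilter("ignore", RuntimeWarning)
                cls_stat = stat(mat[rows], axis=0)
            cls_fill = np.where(observed_in_both, cls_stat, global_fill)
            block = filled[rows]
            block[miss[rows]] = np.broadcast_to(cls_fill, block.shape)[miss[rows]]
            filled[rows] = block
        out = pd.DataFrame(filled, columns=values.columns, index=values.index)
    else:
        raise ConfigurationError(f"unknown imputation strategy {strategy!r}")
    merged = dict(raw.imputed_counts)
    merged.update(counts)
    return RawTable(values=out, labels=raw.labels, label_column=raw.label_column,
                    nominal_encodings=dict(raw.nominal_encodings),
                    imputed_counts=merged, normalization=raw.normalization)


def normalize(raw: RawTable, method: str = "minmax") -> RawTable:
    """Rescale each feature; parameters are learned once on the full matrix.

    ``minmax`` (default) maps to [0,1]; constant features map to 0.
    ``zscore`` standardizes (constant features map to 0).  ``none`` is the
    identity.  The learned parameters are stored on the returned table so
    new samples can be transformed identically at prediction time.
    """
    values = raw.values
    names = [str(c) for c in values.columns]
    if method == "none":
        out, params = values.copy(), {"method": "none"}
    elif method == "minmax":
        mat = values.to_numpy(dtype=float)
        lo, hi = mat.min(axis=0), mat.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        out = pd.DataFrame((mat - lo) / span, columns=values.columns,
                           index=values.index)
        params = {"method": "minmax", "min": dict(zip(names, lo.tolist())),
                  "max": dict(zip(names, hi.tolist()))}
    elif method == "zscore":
        mat = values.to_numpy(dtype=float)
        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        out = pd.DataFrame((mat - mu) / sd, columns=values.columns,
                           index=values.index)
        params = {"method": "zscore", "mean": dict(zip(names, mu.tolist())),
                  "std": dict(zip(names, sd.tolist()))}
    else:
        raise ConfigurationError(f"unknown normalization method {method!r}")
    return RawTable(values=out, labels=raw.labels, label_column=raw.label_column,
                    nominal_encodings=dict(raw.nominal_encodings),
                    imputed_counts=dict(raw.imputed_counts), normalization=params)


def merge_duplicate_features(raw: RawTable) -> Dataset:
    """Average columns that share a feature name and emit the final Dataset.

    Duplicate-named columns (e.g. multiple probes mapping to one gene) are
    replaced by their element-wise mean, keeping the position of the first
    occurrence.  Labels are mapped to {0,1} with the minority class as the
    positive class.
    """
    values = raw.values
    names = [str(c) for c in values.columns]
    seen: dict[str, list[int]] = {}
    order: list[str] = []
    for i, nm in enumerate(names):
        if nm not in seen:
            seen[nm] = []
            order.append(nm)
        seen[nm].append(i)
    mat = values.to_numpy(dtype=float)
    cols = [mat[:, seen[nm]].mean(axis=1) for nm in order]
    X = np.column_stack(cols) if cols else np.empty((mat.shape[0], 0))
    y, positive = _binary_labels(raw)
    return Dataset(X=X, y=y, feature_names=order, positive_label=positive,
                   sample_ids=raw.sample_ids)


def preprocess(raw: RawTable, impute: str = "median",
               norm: str = "minmax") -> tuple[Dataset, dict]:
    """Run the full chain: encode -> impute -> normalize -> merge duplicates.

    Returns the clean :class:`Dataset` and a JSON-serializable report of the
    nominal encodings, imputation counts and merged duplicate groups.
    """
    step = encode_nominal(raw)
    step = impute_missing(step, strategy=impute)
    step = normalize(step, method=norm)
    names = step.feature_names
    dupes = {nm: names.count(nm) for nm in set(names) if names.count(nm) > 1}
    ds = merge_duplicate_features(step)
    report = {
        "nominal_encodings": step.nominal_encodings,
        "imputed_counts": step.imputed_counts,
        "normalization": (step.normalization or {}).get("method"),
        "merged_duplicates": dupes,
        "positive_label": str(ds.positive_label),
        "n_samples": ds.n_samples,
        "n_features": ds.n_features,
    }
    return ds, report


def write_report(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
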