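"""Tabular data container, typing, file I/O and cross-validation splitting.

The central object is :class:`Dataset`: an N x M value matrix with an
explicit boolean missing-value mask, per-feature type tags (``continuous``
or ``discrete``), and an integer class-label vector.  Missingness lives in
the mask, never in a sentinel value, so continuous features may take any
real value.  Discrete features (including string categories read from
files) are stored as non-negative integer codes; the original category
labels are retained for round-tripping.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

CONTINUOUS = "continuous"
DISCRETE = "discrete"

#: columns with at most this many distinct integral values are inferred discrete
DISCRETE_INFERENCE_MAX_LEVELS = 10


class DataError(ValueError):
    """Raised for malformed input tables or contract violations."""


@dataclass
class Dataset:
    """A feature matrix with missing mask, feature types and class labels.

    Parameters
    ----------
    X : ndarray of shape (N, M), float
        Feature values.  Entries where ``mask`` is True are undefined.
    mask : ndarray of shape (N, M), bool
        True marks a missing cell.
    feature_types : list of str
        ``"continuous"`` or ``"discrete"`` per column.
    y : ndarray of shape (N,), int
        Class codes 0..C-1.  Never missing.
    feature_names : list of str
    label_names : list of str
        Original class category labels, indexed by class code.
    categories : dict
        For discrete columns read from string data: column index ->
        list of original category labels, indexed by integer code.
    record_ids : ndarray of shape (N,), int
        Positions in the parent table; used to recombine subsets.
    """

    X: np.ndarray
    mask: np.ndarray
    feature_types: list[str]
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    label_names: list[str] = field(default_factory=list)
    categories: dict[int, list[str]] = field(default_factory=dict)
    name: str = "dataset"
    record_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise DataError("feature matrix must be 2-D")
        n, m = self.X.shape
        if self.mask.shape != (n, m):
            raise DataError("mask shape must match feature matrix")
        if len(self.feature_types) != m:
            raise DataError("one type tag required per feature")
        bad = set(self.feature_types) - {CONTINUOUS, DISCRETE}
        if bad:
            raise DataError(f"unknown feature types: {sorted(bad)}")
        if self.y.shape != (n,):
            raise DataError("labels must be one per record")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(m)]
        if not self.label_names:
            self.label_names = [str(c) for c in sorted(set(self.y.tolist()))] or ["0"]
        if self.record_ids is None:
            self.record_ids = np.arange(n)
        else:
            self.record_ids = np.asarray(self.record_ids, dtype=int)

    # -- basic geometry -------------------------------------------------
    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.y))

    @property
    def continuous_indices(self) -> list[int]:
        return [j for j, t in enumerate(self.feature_types) if t == CONTINUOUS]

    @property
    def discrete_indices(self) -> list[int]:
        return [j for j, t in enumerate(self.feature_types) if t == DISCRETE]

    def is_complete(self) -> bool:
        return not self.mask.any()

    def copy(self) -> "Dataset":
        return replace(
            self,
            X=self.X.copy(),
            mask=self.mask.copy(),
            feature_types=list(self.feature_types),
            y=self.y.copy(),
            feature_names=list(self.feature_names),
            label_names=list(self.label_names),
            categories={k: list(v) for k, v in self.categories.items()},
            record_ids=self.record_ids.copy(),
        )

    def take(self, idx: np.ndarray) -> "Dataset":
        """Row subset preserving record identity."""
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            X=self.X[idx].copy(),
            mask=self.mask[idx].copy(),
            y=self.y[idx].copy(),
            record_ids=self.record_ids[idx].copy(),
        )

    def require_supervised(self) -> None:
        """Check N >= 1, M >= 1, C >= 2 before a supervised operation."""
        if self.n_records < 1 or self.n_features < 1:
            raise DataError("supervised operation needs at least one record and feature")
        if self.n_classes < 2:
            raise DataError("supervised operation needs at least two classes")


@dataclass
class DataSplit:
    """One cross-validation fold: disjoint train/test partition of a parent."""

    train: Dataset
    test: Dataset
    fold_index: int
    seed: int


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"?", ""}


def _infer_type(values: list[str]) -> str:
    """Discrete iff all non-missing values are integral with few levels."""
    seen = set()
    for v in values:
        try:
            x = float(v)
        except ValueError:
            return DISCRETE  # non-numeric strings are categorical
        if x != int(x):
            return CONTINUOUS
        seen.add(x)
    if 0 < len(seen) <= DISCRETE_INFERENCE_MAX_LEVELS:
        return DISCRETE
    return CONTINUOUS


def read_table(path, schema=None, class_column=None, name=None) -> Dataset:
    """Read a CSV or ARFF table into a :class:`Dataset`.

    ``"?"`` and empty cells become missing.  ``schema`` is an optional list
    of type tags for the feature columns; without it, CSV types are
    inferred (a column is discrete iff all non-missing values are integral
    with at most 10 distinct levels) and ARFF types come from the
    ``@attribute`` declarations.  ``class_column`` names or indexes the
    label column; default is the last column.
    """
    path = str(path)
    if path.lower().endswith(".arff"):
        return _read_arff(path, class_column=class_column, name=name)
    return _read_csv(path, schema=schema, class_column=class_column, name=name)


def _read_csv(path, schema=None, class_column=None, name=None) -> Dataset:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise DataError(f"{path}: empty file")
    header, body = rows[0], rows[1:]
    if not body:
        raise DataError(f"{path}: no data rows")
    ncol = len(header)
    if class_column is None:
        class_idx = ncol - 1
    elif isinstance(class_column, int):
        class_idx = class_column % ncol
    else:
        try:
            class_idx = header.index(class_column)
        except ValueError:
            raise DataError(f"{path}: class column {class_column!r} not in header")
    feat_cols = [j for j in range(ncol) if j != class_idx]

    raw_labels = []
    for i, row in enumerate(body):
        if len(row) != ncol:
            raise DataError(f"{path}: row {i} has {len(row)} cells, expected {ncol}")
        cell = row[class_idx].strip()
        if cell in _MISSING_TOKENS:
            raise DataError(f"{path}: missing class value at row {i}")
        raw_labels.append(cell)

    if schema is not None and len(schema) != len(feat_cols):
        raise DataError("schema length must equal number of feature columns")

    col_types: list[str] = []
    for pos, j in enumerate(feat_cols):
        if schema is not None:
            col_types.append(schema[pos])
        else:
            non_missing = [r[j].strip() for r in body if r[j].strip() not in _MISSING_TOKENS]
            col_types.append(_infer_type(non_missing) if non_missing else CONTINUOUS)

    n, m = len(body), len(feat_cols)
    X = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    categories: dict[int, list[str]] = {}
    for pos, j in enumerate(feat_cols):
        cells = [r[j].strip() for r in body]
        numeric = True
        for c in cells:
            if c in _MISSING_TOKENS:
                continue
            try:
                float(c)
            except ValueError:
                numeric = False
                break
        if numeric:
            for i, c in enumerate(cells):
                if c in _MISSING_TOKENS:
                    mask[i, pos] = True
                else:
                    try:
                        X[i, pos] = float(c)
                    except ValueError:
                        raise DataError(
                            f"{path}: cell ({i}, {header[j]!r}) = {c!r} "
                            f"not parseable as {col_types[pos]}"
                        )
        else:
            if col_types[pos] == CONTINUOUS:
                bad = next(c for c in cells if c not in _MISSING_TOKENS and not _is_float(c))
                raise DataError(
                    f"{path}: column {header[j]!r} declared continuous but "
                    f"contains non-numeric cell {bad!r}"
                )
            levels = sorted({c for c in cells if c not in _MISSING_TOKENS})
            code = {lv: k for k, lv in enumerate(levels)}
            categories[pos] = levels
            for i, c in enumerate(cells):
                if c in _MISSING_TOKENS:
                    mask[i, pos] = True
                else:
                    X[i, pos] = code[c]

    levels = sorted(set(raw_labels))
    label_code = {lv: k for k, lv in enumerate(levels)}
    y = np.array([label_code[c] for c in raw_labels])
    return Dataset(
        X=X,
        mask=mask,
        feature_types=col_types,
        y=y,
        feature_names=[header[j] for j in feat_cols],
        label_names=levels,
        categories=categories,
        name=name or path,
    )


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_arff(path, class_column=None, name=None) -> Dataset:
    from scipy.io import arff as scipy_arff

    data, meta = scipy_arff.loadarff(path)
    names = list(meta.names())
    if class_column is None:
        class_name = names[-1]
    elif isinstance(class_column, int):
        class_name = names[class_column % len(names)]
    else:
        class_name = class_column
    feat_names = [c for c in names if c != class_name]

    raw_labels = data[class_name]
    if raw_labels.dtype.kind == "S":
        raw = [v.decode() for v in raw_labels]
        if any(v == "?" for v in raw):
            raise DataError(f"{path}: missing class value")
        levels = sorted(set(raw))
        y = np.array([levels.index(v) for v in raw])
    else:
        if np.isnan(raw_labels.astype(float)).any():
            raise DataError(f"{path}: missing class value")
        vals = raw_labels.astype(float)
        levels = [str(v) for v in sorted(set(vals.tolist()))]
        lut = {float(v): k for k, v in enumerate(sorted(set(vals.tolist())))}
        y = np.array([lut[v] for v in vals])

    n, m = len(data), len(feat_names)
    X = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    types: list[str] = []
    categories: dict[int, list[str]] = {}
    for pos, col in enumerate(feat_names):
        attr_type = meta[col][0]  # 'numeric' or 'nominal' per declaration
        vals = data[col]
        if attr_type == "numeric":
            types.append(CONTINUOUS)
            arr = vals.astype(float)
            mask[:, pos] = np.isnan(arr)
            X[:, pos] = np.where(mask[:, pos], 0.0, arr)
        else:
            types.append(DISCRETE)
            decoded = [v.decode() if isinstance(v, bytes) else str(v) for v in vals]
            levels_c = sorted({v for v in decoded if v != "?"})
            categories[pos] = levels_c
            code = {lv: k for k, lv in enumerate(levels_c)}
            for i, v in enumerate(decoded):
                if v == "?":
                    mask[i, pos] = True
                else:
                    X[i, pos] = code[v]
    return Dataset(
        X=X,
        mask=mask,
        feature_types=types,
        y=y,
        feature_names=feat_names,
        label_names=levels,
        categories=categories,
        name=name or path,
    )


def write_table(d: Dataset, path) -> None:
    """Write a Dataset as CSV with ``?`` marking missing cells.

    Round-trips bit-exactly with :func:`read_table` for numeric columns
    (``repr`` of the float is written) and restores original category
    labels for coded discrete columns.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(d.feature_names) + ["class"])
        for i in range(d.n_records):
            row = []
            for j in range(d.n_features):
                if d.mask[i, j]:
                    row.append("?")
                elif j in d.categories:
                    row.append(d.categories[j][int(d.X[i, j])])
                else:
                    v = float(d.X[i, j])
                    row.append(repr(int(v)) if v == int(v) else repr(v))
            row.append(d.label_names[d.y[i]])
            w.writerow(row)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def kfold_splits(d: Dataset, k: int = 5, seed: int = 0) -> list[DataSplit]:
    """Stratified k-fold partition into (train, test) splits.

    Falls back to a plain shuffled partition with a warning if any class
    has fewer members than k.
    """
    if k < 2:
        raise DataError("k must be at least 2")
    if d.n_records < k:
        raise DataError("fewer records than folds")
    _, counts = np.unique(d.y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"a class has fewer than {k} members; folds are not stratified",
            UserWarning,
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(d.X)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(d.X, d.y)
    return [
        DataSplit(train=d.take(tr), test=d.take(te), fold_index=f, seed=seed)
        for f, (tr, te) in enumerate(folds)
    ]


def split_complete_incomplete(d: Dataset) -> tuple[Dataset, Dataset]:
    """Partition records into (no missing cells, at least one missing cell).

    Record order within each subset is preserved and ``record_ids`` allow
    exact recombination.  Raises if the complete subset would be empty,
    since nothing could be fitted downstream.
    """
    has_missing = d.mask.any(axis=1)
    complete_idx = np.flatnonzero(~has_missing)
    incomplete_idx = np.flatnonzero(has_missing)
    if complete_idx.size == 0:
        raise DataError("no complete records; model fitting is impossible")
    return d.take(complete_idx), d.take(incomplete_idx)


def recombine(a: Dataset, b: Dataset) -> Dataset:
    """Merge two disjoint subsets back into original record order."""
    X = np.vstack([a.X, b.X])
    mask = np.vstack([a.mask, b.mask])
    y = np.concatenate([a.y, b.y])
    ids = np.concatenate([a.record_ids, b.record_ids])
    order = np.argsort(ids, kind="stable")
    return Dataset(
        X=X[order],
        mask=mask[order],
        feature_types=list(a.feature_types),
        y=y[order],
        feature_names=list(a.feature_names),
        label_names=list(a.label_names),
        categories={k: list(v) for k, v in a.categories.items()},
        name=a.name,
        record_ids=ids[order],
    )
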