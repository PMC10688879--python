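"""Missing-value imputation on mixed-type data: mean/mode, KNN, CART.

All three imputers are fitted on fully observed records only and then
complete incomplete records one at a time, each missing feature estimated
independently from the record's observed features.  Observed cells are
never altered.  The class label is never used as a predictor.

* ``mean_mode`` stores the column mean (continuous) or mode (discrete).
* ``knn`` keeps the complete records as a reference set and imputes from
  the k nearest under an HEOM-style distance: range-normalised absolute
  difference for continuous features, 0/1 mismatch for discrete ones,
  summed in quadrature over the features observed in the query record.
  Continuous targets take the neighbours' mean, discrete targets their
  majority vote (ties: smallest category code; equal distances: smallest
  reference index).
* ``cart`` fits one decision tree per feature on the complete subset with
  that feature as target and all other features as predictors —
  a regression tree for continuous targets, a classification tree for
  discrete ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data_model import CONTINUOUS, DataError, Dataset

MEAN_MODE = "mean_mode"
KNN = "knn"
CART = "cart"


@dataclass
class ImputerModel:
    """A fitted imputer covering every feature of the training schema."""

    method: str
    training_feature_types: list[str]
    feature_names: list[str]
    statistics: np.ndarray | None = None      # mean_mode
    reference: np.ndarray | None = None       # knn: complete records
    ranges: np.ndarray | None = None          # knn: per-feature value ranges
    k: int = 5
    trees: dict[int, object] = field(default_factory=dict)  # cart: per-target tree
    predictor_fill: np.ndarray | None = None  # cart: mean/mode per column
    seed: int = 0


def fit_imputer(complete: Dataset, method: str, k: int = 5, seed: int = 0) -> ImputerModel:
    """Fit an imputer of the given method on a fully observed dataset."""
    if complete.n_records == 0:
        raise DataError("cannot fit an imputer on an empty complete subset")
    if not complete.is_complete():
        raise DataError("imputer must be fitted on records with no missing cells")

    model = ImputerModel(
        method=method,
        training_feature_types=list(complete.feature_types),
        feature_names=list(complete.feature_names),
        k=k,
        seed=seed,
    )
    X = complete.X
    if method == MEAN_MODE:
        stats = np.empty(complete.n_features)
        for j, t in enumerate(complete.feature_types):
            col = X[:, j]
            if t == CONTINUOUS:
                stats[j] = col.mean()
            else:
                codes, counts = np.unique(col, return_counts=True)
                stats[j] = codes[np.argmax(counts)]  # smallest code wins ties
        model.statistics = stats
    elif method == KNN:
        if k > complete.n_records:
            raise DataError(f"k={k} exceeds the {complete.n_records} complete records")
        model.reference = X.copy()
        rng = X.max(axis=0) - X.min(axis=0)
        model.ranges = rng
    elif method == CART:
        if complete.n_features < 2:
            raise DataError("cart imputation needs at least two features")
        fill = np.empty(complete.n_features)
        for j, t in enumerate(complete.feature_types):
            col = X[:, j]
            if t == CONTINUOUS:
                fill[j] = col.mean()
            else:
                codes, counts = np.unique(col, return_counts=True)
                fill[j] = codes[np.argmax(counts)]
        model.predictor_fill = fill
        for j, t in enumerate(complete.feature_types):
            others = [c for c in range(complete.n_features) if c != j]
            if t == CONTINUOUS:
                tree = DecisionTreeRegressor(min_samples_leaf=5, random_state=seed)
            else:
                tree = DecisionTreeClassifier(
                    criterion="gini", min_samples_leaf=5, random_state=seed
                )
            tree.fit(X[:, others], X[:, j])
            model.trees[j] = tree
    else:
        raise DataError(f"unknown imputation method {method!r}")
    return model


def _heom_distances(model: ImputerModel, values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Distance from a partial record to every reference record.

    Only the query's observed features contribute.  Continuous features
    use |a-b|/range (range from the fitting set; zero-range features
    score 0 on equality, 1 otherwise); discrete features score 0/1.
    """
    ref = model.reference
    d2 = np.zeros(ref.shape[0])
    for j in np.flatnonzero(observed):
        diff = ref[:, j] - values[j]
        if model.training_feature_types[j] == CONTINUOUS:
            rng = model.ranges[j]
            if rng > 0:
                per = np.abs(diff) / rng
            else:
                per = (diff != 0).astype(float)
        else:
            per = (diff != 0).astype(float)
        d2 += per**2
    return np.sqrt(d2)


def _vote(codes: np.ndarray) -> float:
    """Majority vote; ties broken by the smallest category code."""
    uniq, counts = np.unique(codes, return_counts=True)
    return float(uniq[np.argmax(counts)])


def impute_record(model: ImputerModel, values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Complete one record.

    ``values`` holds the record's feature values (entries where
    ``observed`` is False are ignored); returns a fully observed copy.
    """
    values = np.asarray(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    out = values.copy()
    missing = np.flatnonzero(~observed)
    if missing.size == 0:
        return out

    if model.method == MEAN_MODE:
        out[missing] = model.statistics[missing]
        return out

    if not observed.any():
        raise DataError(f"{model.method} imputation needs at least one observed feature")

    if model.method == KNN:
        dist = _heom_distances(model, values, observed)
        order = np.argsort(dist, kind="stable")  # ties -> smallest reference index
        nbr = model.reference[order[: model.k]]
        for j in missing:
            if model.training_feature_types[j] == CONTINUOUS:
                out[j] = nbr[:, j].mean()
            else:
                out[j] = _vote(nbr[:, j])
        return out

    if model.method == CART:
        for j in missing:
            others = [c for c in range(len(model.training_feature_types)) if c != j]
            row = values[others].copy()
            # a tree cannot be routed past a split on an unobserved predictor;
            # such predictors take the fitting-set mean/mode
            for pos, c in enumerate(others):
                if not observed[c]:
                    row[pos] = model.predictor_fill[c]
            out[j] = float(model.trees[j].predict(row.reshape(1, -1))[0])
        return out

    raise DataError(f"unknown imputation method {model.method!r}")


def impute_dataset(model: ImputerModel, incomplete: Dataset) -> Dataset:
    """Complete every record of a dataset; observed cells are untouched."""
    if list(incomplete.feature_types) != list(model.training_feature_types):
        raise DataError("feature types of the data do not match the fitted imputer")
    out = incomplete.copy()
    for i in range(incomplete.n_records):
        if incomplete.mask[i].any():
            out.X[i] = impute_record(model, incomplete.X[i], ~incomplete.mask[i])
    out.mask[:] = False
    return out
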