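"""Classifier evaluation of pipeline outputs and statistical comparison.

Two classifiers are supported: an RBF-kernel support vector machine and an
entropy-criterion decision tree with minimal-cost-complexity pruning (an
approximation of C4.5's multiway, error-based-pruned trees — documented as
such).  Accuracy (fraction of correct test predictions) is the sole metric.

Feature encoding: interval codes produced by the discretizers are ordered
by construction, so discrete features are presented to the learners as
ordinal integer codes by default; one-hot encoding is available as an
option.  Continuous features are standardised (train-fitted) for the SVM.

Arms of an experiment (order/baseline x discretizer x imputer x
classifier) are compared with the two-sided Wilcoxon rank-sum test on
their per-cell or per-dataset mean accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.preprocessing import OneHotEncoder
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import CONTINUOUS, DataError, Dataset, kfold_splits
from .discretize import CHIMERGE, MDLP, ChiMergeParams
from .impute import CART, KNN, MEAN_MODE
from .missingness import MissingSpec, derive_seed
from .pipeline import (
    ORDER_A,
    ORDER_B,
    PipelineResult,
    prepare_baselines,
    run_order_A,
    run_order_B,
    transform_test,
)

SVM_RBF = "svm_rbf"
C45_TREE = "c45_tree"


@dataclass
class ClassifierSpec:
    """Classifier kind plus hyperparameters and encoding choice."""

    kind: str = SVM_RBF
    cost: float = 1.0           # SVM regularisation C
    gamma: str | float = "scale"  # RBF width; "scale" = 1/(M * var)
    ccp_alpha: float = 0.01     # tree pruning strength
    min_samples_leaf: int = 2
    encoding: str = "ordinal"   # "ordinal" | "onehot" for discrete features
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (SVM_RBF, C45_TREE):
            raise DataError(f"unknown classifier kind {self.kind!r}")
        if self.cost <= 0 or self.ccp_alpha < 0 or self.min_samples_leaf < 1:
            raise DataError("classifier hyperparameters must be positive")
        if self.encoding not in ("ordinal", "onehot"):
            raise DataError(f"unknown encoding {self.encoding!r}")


def _encode(train: Dataset, test: Dataset, spec: ClassifierSpec):
    """Train-fitted feature encoding shared by train and test."""
    Xtr, Xte = train.X.copy(), test.X.copy()
    cont = train.continuous_indices
    if cont and spec.kind == SVM_RBF:
        mu = Xtr[:, cont].mean(axis=0)
        sd = Xtr[:, cont].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr[:, cont] = (Xtr[:, cont] - mu) / sd
        Xte[:, cont] = (Xte[:, cont] - mu) / sd
    disc = train.discrete_indices
    if disc and spec.encoding == "onehot":
        enc = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        tr_d = enc.fit_transform(Xtr[:, disc])
        te_d = enc.transform(Xte[:, disc])
        keep = [j for j in range(train.n_features) if j not in disc]
        Xtr = np.column_stack([Xtr[:, keep], tr_d]) if keep else tr_d
        Xte = np.column_stack([Xte[:, keep], te_d]) if keep else te_d
    return Xtr, Xte


def train_and_score(train: Dataset, test: Dataset, spec: ClassifierSpec) -> float:
    """Fit the classifier on train, return test accuracy."""
    if not train.is_complete() or not test.is_complete():
        raise DataError("classifier needs complete train and test data")
    if list(train.feature_types) != list(test.feature_types):
        raise DataError("train and test feature spaces differ")
    if train.n_classes < 2:
        warnings.warn(
            "single-class training set; predicting that class everywhere",
            UserWarning,
            stacklevel=2,
        )
        return float(np.mean(test.y == train.y[0]))

    Xtr, Xte = _encode(train, test, spec)
    if spec.kind == SVM_RBF:
        clf = SVC(kernel="rbf", C=spec.cost, gamma=spec.gamma, random_state=spec.seed)
    else:
        clf = DecisionTreeClassifier(
            criterion="entropy",
            ccp_alpha=spec.ccp_alpha,
            min_samples_leaf=spec.min_samples_leaf,
            random_state=spec.seed,
        )
    clf.fit(Xtr, train.y)
    return float(np.mean(clf.predict(Xte) == test.y))


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "dataset", "arm", "order", "disc_method", "imp_method",
    "classifier", "rate", "rep", "fold", "accuracy",
]


@dataclass
class EvaluationReport:
    """Tidy per-cell accuracy rows with aggregation helpers."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_REPORT_COLUMNS)
    )

    def add(self, **kw) -> None:
        if not 0.0 <= kw["accuracy"] <= 1.0:
            raise DataError("accuracy must lie in [0, 1]")
        self.rows.loc[len(self.rows)] = [kw.get(c) for c in _REPORT_COLUMNS]

    def mean_by_rate(self) -> pd.DataFrame:
        """Mean accuracy per (arm, rate) over reps x folds."""
        return (
            self.rows.groupby(["arm", "rate"], dropna=False)["accuracy"]
            .mean()
            .reset_index()
        )

    def mean_by_arm(self) -> pd.DataFrame:
        """Per-arm mean over all rates, reps and folds."""
        return self.rows.groupby("arm")["accuracy"].mean().reset_index()

    def arm_values(self, arm: str) -> np.ndarray:
        return self.rows.loc[self.rows["arm"] == arm, "accuracy"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def summary_markdown(self) -> str:
        """Arms as columns, datasets as rows, mean accuracy in the cells."""
        pivot = self.rows.pivot_table(
            index="dataset", columns="arm", values="accuracy", aggfunc="mean"
        )
        return pivot.round(3).to_markdown()


def _arm_name(order: str, disc: str | None, imp: str | None, clf: str) -> str:
    parts = [order]
    if disc:
        parts.append(disc)
    if imp:
        parts.append(imp)
    parts.append(clf)
    return "+".join(parts)


def run_experiment(
    dataset: Dataset,
    *,
    folds: int = 5,
    rates: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    reps: int = 10,
    disc_methods: tuple[str, ...] = (MDLP, CHIMERGE),
    imp_methods: tuple[str, ...] = (MEAN_MODE, CART, KNN),
    classifiers: tuple[ClassifierSpec, ...] | None = None,
    orders: tuple[str, ...] = (ORDER_A, ORDER_B),
    include_baselines: bool = True,
    chimerge_params: ChiMergeParams | None = None,
    imp_k: int = 5,
    base_seed: int = 0,
) -> EvaluationReport:
    """Run the full folds x rates x reps x methods x orders grid.

    Each grid cell runs one pipeline order (or baseline) on one fold's
    training set with one MCAR injection, then scores each classifier on
    the transformed test fold.  Cell failures are recorded and skipped.
    """
    if classifiers is None:
        classifiers = (ClassifierSpec(kind=SVM_RBF), ClassifierSpec(kind=C45_TREE))
    report = EvaluationReport()
    splits = kfold_splits(dataset, k=folds, seed=base_seed)

    def score(result: PipelineResult, split, clf: ClassifierSpec) -> float:
        test_t = transform_test(result, split.test)
        return train_and_score(result.train_processed, test_t, clf)

    for split in splits:
        if include_baselines:
            b1 = prepare_baselines(split, 1)
            for clf in classifiers:
                report.add(
                    dataset=dataset.name, arm=_arm_name("baseline1", None, None, clf.kind),
                    order="baseline1", disc_method=None, imp_method=None,
                    classifier=clf.kind, rate=0.0, rep=0,
                    fold=split.fold_index, accuracy=score(b1, split, clf),
                )
            for disc in disc_methods:
                b2 = prepare_baselines(split, 2, disc_method=disc, disc_params=chimerge_params)
                for clf in classifiers:
                    report.add(
                        dataset=dataset.name, arm=_arm_name("baseline2", disc, None, clf.kind),
                        order="baseline2", disc_method=disc, imp_method=None,
                        classifier=clf.kind, rate=0.0, rep=0,
                        fold=split.fold_index, accuracy=score(b2, split, clf),
                    )
        for rate in rates:
            for rep in range(reps):
                seed = derive_seed(base_seed, rate, rep * folds + split.fold_index)
                spec = MissingSpec(rate=rate, seed=seed)
                if include_baselines:
                    for imp in imp_methods:
                        try:
                            b3 = prepare_baselines(
                                split, 3, imp_method=imp, spec=spec,
                                imp_k=imp_k, imp_seed=seed,
                            )
                        except DataError as exc:  # cell recorded and skipped
                            warnings.warn(f"baseline3 cell failed: {exc}", stacklevel=2)
                            continue
                        for clf in classifiers:
                            report.add(
                                dataset=dataset.name,
                                arm=_arm_name("baseline3", None, imp, clf.kind),
                                order="baseline3", disc_method=None, imp_method=imp,
                                classifier=clf.kind, rate=rate, rep=rep,
                                fold=split.fold_index, accuracy=score(b3, split, clf),
                            )
                for order, runner in ((ORDER_A, run_order_A), (ORDER_B, run_order_B)):
                    if order not in orders:
                        continue
                    for disc in disc_methods:
                        for imp in imp_methods:
                            try:
                                result = runner(
                                    split, disc, imp, spec,
                                    disc_params=chimerge_params,
                                    imp_k=imp_k, imp_seed=seed,
                                )
                            except DataError as exc:
                                warnings.warn(f"{order} cell failed: {exc}", stacklevel=2)
                                continue
                            for clf in classifiers:
                                report.add(
                                    dataset=dataset.name,
                                    arm=_arm_name(order, disc, imp, clf.kind),
                                    order=order, disc_method=disc, imp_method=imp,
                                    classifier=clf.kind, rate=rate, rep=rep,
                                    fold=split.fold_index,
                                    accuracy=score(result, split, clf),
                                )
    return report


# ---------------------------------------------------------------------------
# statistical comparison
# ---------------------------------------------------------------------------


@dataclass
class ArmComparison:
    statistic: float   # rank sum W of arm_a
    p_value: float
    direction: int     # sign of mean(arm_a) - mean(arm_b)
    arm_a: str = ""
    arm_b: str = ""


def rank_sum_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Rank sum W of sample ``a`` in the pooled ranking (midranks for ties)."""
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    # midranks for ties
    for v in np.unique(pooled):
        sel = pooled == v
        if sel.sum() > 1:
            ranks[sel] = ranks[sel].mean()
    return float(ranks[: len(a)].sum())


def compare_arms(report: EvaluationReport, arm_a: str, arm_b: str) -> ArmComparison:
    """Two-sided Wilcoxon rank-sum test between two arms' accuracies."""
    a = report.arm_values(arm_a)
    b = report.arm_values(arm_b)
    if len(a) < 2 or len(b) < 2:
        raise DataError("each arm needs at least two observations")
    w = rank_sum_statistic(a, b)
    direction = int(np.sign(a.mean() - b.mean()))
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("identical constant samples; p = 1 by convention", stacklevel=2)
        return ArmComparison(w, 1.0, 0, arm_a, arm_b)
    _, p = mannwhitneyu(a, b, alternative="two-sided")
    return ArmComparison(w, float(p), direction, arm_a, arm_b)
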