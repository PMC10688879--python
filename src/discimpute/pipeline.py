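"""The two order-of-combination preprocessing procedures and baselines.

Order A (discretize, then impute)
    Inject MCAR missingness into the training set, partition it into
    complete and incomplete record subsets, fit the cutoff scheme on the
    complete subset only, code the incomplete subset with those cuts
    (missing cells untouched), fit the imputer on the coded complete
    subset, impute the coded incomplete subset (so estimates are interval
    codes), and recombine.  The test set is later coded with the
    complete-subset scheme.

Order B (impute, then discretize)
    Inject, partition, fit the imputer on the continuous complete subset,
    impute continuous values, recombine, then fit the cutoff scheme on
    the whole completed training set and code it.  The test set is coded
    with that scheme.

Baselines
    1: training data untouched (continuous, complete, no scheme).
    2: discretization only — scheme fitted on the full complete training
       set, no missingness.
    3: missingness plus imputation of continuous values, no
       discretization.

All fitting uses training data only; the test set never influences the
scheme or the imputer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import DataError, DataSplit, Dataset, recombine, split_complete_incomplete
from .discretize import CutoffScheme, apply_scheme, fit_scheme
from .impute import fit_imputer, impute_dataset
from .missingness import MissingSpec, inject_mcar

ORDER_A = "A_discretize_then_impute"
ORDER_B = "B_impute_then_discretize"
BASELINE_1 = "baseline1"
BASELINE_2 = "baseline2"
BASELINE_3 = "baseline3"


@dataclass
class PipelineResult:
    """A processed training set plus everything needed to transform test data."""

    train_processed: Dataset
    scheme: CutoffScheme | None
    order: str
    provenance: dict = field(default_factory=dict)


def _inject(train: Dataset, spec: MissingSpec | None) -> Dataset:
    if spec is None:
        return train.copy()
    return inject_mcar(train, spec)


def run_order_A(
    split: DataSplit,
    disc_method: str,
    imp_method: str,
    spec: MissingSpec | None,
    disc_params=None,
    imp_k: int = 5,
    imp_seed: int = 0,
) -> PipelineResult:
    """Discretize first, impute second."""
    if not split.train.is_complete():
        raise DataError("training data must be complete before injection")
    injected = _inject(split.train, spec)
    if injected.is_complete():
        # rate -> 0 limit: no incomplete subset, imputation is a no-op
        scheme = fit_scheme(injected, disc_method, disc_params)
        processed = apply_scheme(injected, scheme)
    else:
        complete, incomplete = split_complete_incomplete(injected)
        scheme = fit_scheme(complete, disc_method, disc_params)
        complete_d = apply_scheme(complete, scheme)
        incomplete_d = apply_scheme(incomplete, scheme)
        imputer = fit_imputer(complete_d, imp_method, k=imp_k, seed=imp_seed)
        incomplete_filled = impute_dataset(imputer, incomplete_d)
        processed = recombine(complete_d, incomplete_filled)
    return PipelineResult(
        train_processed=processed,
        scheme=scheme,
        order=ORDER_A,
        provenance={
            "disc_method": disc_method,
            "imp_method": imp_method,
            "missing": None if spec is None else vars(spec).copy(),
            "imp_k": imp_k,
            "imp_seed": imp_seed,
        },
    )


def run_order_B(
    split: DataSplit,
    disc_method: str,
    imp_method: str,
    spec: MissingSpec | None,
    disc_params=None,
    imp_k: int = 5,
    imp_seed: int = 0,
) -> PipelineResult:
    """Impute first, discretize second."""
    if not split.train.is_complete():
        raise DataError("training data must be complete before injection")
    injected = _inject(split.train, spec)
    if injected.is_complete():
        completed = injected
    else:
        complete, incomplete = split_complete_incomplete(injected)
        imputer = fit_imputer(complete, imp_method, k=imp_k, seed=imp_seed)
        incomplete_filled = impute_dataset(imputer, incomplete)
        completed = recombine(complete, incomplete_filled)
    scheme = fit_scheme(completed, disc_method, disc_params)
    processed = apply_scheme(completed, scheme)
    return PipelineResult(
        train_processed=processed,
        scheme=scheme,
        order=ORDER_B,
        provenance={
            "disc_method": disc_method,
            "imp_method": imp_method,
            "missing": None if spec is None else vars(spec).copy(),
            "imp_k": imp_k,
            "imp_seed": imp_seed,
        },
    )


def prepare_baselines(
    split: DataSplit,
    variant: int,
    disc_method: str | None = None,
    imp_method: str | None = None,
    spec: MissingSpec | None = None,
    disc_params=None,
    imp_k: int = 5,
    imp_seed: int = 0,
) -> PipelineResult:
    """The three reference preparations against which orders A/B compare."""
    if variant not in (1, 2, 3):
        raise DataError("baseline variant must be 1, 2 or 3")
    if variant in (1, 2) and spec is not None:
        raise DataError(f"baseline {variant} takes no missingness spec")

    if variant == 1:
        return PipelineResult(
            train_processed=split.train.copy(),
            scheme=None,
            order=BASELINE_1,
            provenance={},
        )
    if variant == 2:
        if disc_method is None:
            raise DataError("baseline 2 needs a discretization method")
        scheme = fit_scheme(split.train, disc_method, disc_params)
        return PipelineResult(
            train_processed=apply_scheme(split.train, scheme),
            scheme=scheme,
            order=BASELINE_2,
            provenance={"disc_method": disc_method},
        )
    # variant 3: inject + impute continuous values, no discretization
    if imp_method is None or spec is None:
        raise DataError("baseline 3 needs an imputation method and a missingness spec")
    injected = inject_mcar(split.train, spec)
    complete, incomplete = split_complete_incomplete(injected)
    imputer = fit_imputer(complete, imp_method, k=imp_k, seed=imp_seed)
    completed = recombine(complete, impute_dataset(imputer, incomplete))
    return PipelineResult(
        train_processed=completed,
        scheme=None,
        order=BASELINE_3,
        provenance={"imp_method": imp_method, "missing": vars(spec).copy()},
    )


def transform_test(result: PipelineResult, test: Dataset) -> Dataset:
    """Apply the training-set scheme to the test set; never refit."""
    if not test.is_complete():
        raise DataError("test data must be complete")
    if result.order in (ORDER_A, ORDER_B, BASELINE_2):
        if result.scheme is None:
            raise DataError(f"{result.order} requires a fitted cutoff scheme")
        return apply_scheme(test, result.scheme)
    return test.copy()
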