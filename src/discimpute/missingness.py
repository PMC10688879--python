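"""MCAR missing-value injection at controlled rates.

Masking positions depend only on the seed — never on feature values or
class labels — which is what "missing completely at random" means.  Labels
are never masked.

Two units of "missing rate" are supported:

* ``record`` (default): exactly ``round(rate * N)`` records are selected
  uniformly at random and ``per_record_features`` distinct features are
  masked in each.  This guarantees a usable complete subset even at a
  50% rate.
* ``cell``: every feature cell is masked independently with probability
  ``rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DataError, Dataset

RECORD = "record"
CELL = "cell"


@dataclass
class MissingSpec:
    """Configuration for one MCAR injection."""

    rate: float
    unit: str = RECORD
    per_record_features: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rate < 1:
            raise DataError("missing rate must lie strictly between 0 and 1")
        if self.unit not in (RECORD, CELL):
            raise DataError(f"unknown missingness unit {self.unit!r}")
        if self.per_record_features < 1:
            raise DataError("per_record_features must be at least 1")


def inject_mcar(d: Dataset, spec: MissingSpec) -> Dataset:
    """Return a copy of a complete dataset with MCAR-masked cells."""
    if not d.is_complete():
        raise DataError("MCAR injection expects a complete dataset")
    if spec.per_record_features > d.n_features:
        raise DataError("per_record_features exceeds the feature count")
    rng = np.random.default_rng(spec.seed)
    out = d.copy()

    if spec.unit == RECORD:
        n_mask = int(round(spec.rate * d.n_records))
        if n_mask < 1:
            raise DataError(
                f"rate {spec.rate} on {d.n_records} records masks no record"
            )
        rows = rng.choice(d.n_records, size=n_mask, replace=False)
        for i in rows:
            cols = rng.choice(d.n_features, size=spec.per_record_features, replace=False)
            out.mask[i, cols] = True
    else:
        out.mask = rng.random(d.mask.shape) < spec.rate
        if bool(out.mask.any(axis=1).all()):
            raise DataError(
                "cell-unit injection left no complete record; "
                "use the record unit or a lower rate"
            )
    return out


def derive_seed(base_seed: int, rate: float, rep: int) -> int:
    """Deterministic per-(rate, repetition) seed below 2**31.

    Any single cell of an experiment grid can be re-run in isolation
    without replaying the whole sequence.
    """
    ss = np.random.SeedSequence(
        entropy=int(base_seed), spawn_key=(int(round(rate * 1000)), int(rep))
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def repetition_suite(
    d: Dataset,
    rates: list[float],
    reps: int = 10,
    base_seed: int = 0,
    unit: str = RECORD,
    per_record_features: int = 1,
) -> list[tuple[float, int, Dataset]]:
    """Independent MCAR injections: ``reps`` variants per missing rate."""
    if reps < 1:
        raise DataError("reps must be at least 1")
    out = []
    for rate in rates:
        for rep in range(reps):
            spec = MissingSpec(
                rate=rate,
                unit=unit,
                per_record_features=per_record_features,
                seed=derive_seed(base_seed, rate, rep),
            )
            out.append((rate, rep, inject_mcar(d, spec)))
    return out


def export_mask(d: Dataset) -> list[tuple[int, str]]:
    """Masked cells as (record index, feature name) pairs, for audit."""
    rows, cols = np.nonzero(d.mask)
    return [(int(i), d.feature_names[j]) for i, j in zip(rows, cols)]
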