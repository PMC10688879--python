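"""Generator of complete, mixed-type, two-class datasets with known truth.

The generator emulates the structure of small clinical tabular benchmarks:
a few hundred to a few thousand records, 8-40 mostly continuous features,
two classes.  Informative continuous features are class-conditional
Gaussians with unit variance and means ``boundary +/- effect_size/2``, so
the Bayes-optimal single cut per informative feature is known analytically
(the midpoint of the class means) — a measurable ground truth for the
discretizers that real benchmark data cannot provide.  Noise features are
class-independent Gaussians; discrete features are three-category
variables with a mild class association so mode imputation and KNN voting
are exercised non-trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .data_model import CONTINUOUS, DISCRETE, DataError, Dataset
from .discretize import CutoffScheme, fit_scheme

#: class-conditional category probabilities for discrete features
_DISCRETE_P0 = np.array([0.5, 0.3, 0.2])
_DISCRETE_P1 = np.array([0.2, 0.3, 0.5])


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    n_records: int = 500
    n_informative_continuous: int = 5
    n_noise_continuous: int = 3
    n_discrete: int = 2
    class_balance: float = 0.5      # prior of class 1
    effect_size: float = 2.0        # standardised mean separation
    boundary_locations: list[float] | None = None
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_records < 20:
            raise DataError("n_records must be at least 20")
        if not 0 < self.class_balance < 1:
            raise DataError("class_balance must lie strictly between 0 and 1")
        if self.effect_size < 0:
            raise DataError("effect_size must be non-negative")
        if self.boundary_locations is None:
            self.boundary_locations = [0.0] * self.n_informative_continuous
        if len(self.boundary_locations) != self.n_informative_continuous:
            raise DataError("one boundary location per informative feature")

    def to_yaml(self) -> str:
        doc = {k: getattr(self, k) for k in (
            "n_records", "n_informative_continuous", "n_noise_continuous",
            "n_discrete", "class_balance", "effect_size",
            "boundary_locations", "seed", "name",
        )}
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        return cls(**yaml.safe_load(text))


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw one complete dataset according to the spec, deterministically."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    y = (rng.random(n) < spec.class_balance).astype(int)

    cols, types, names = [], [], []
    for j in range(spec.n_informative_continuous):
        b = spec.boundary_locations[j]
        mean = np.where(y == 1, b + spec.effect_size / 2, b - spec.effect_size / 2)
        cols.append(mean + rng.standard_normal(n))
        types.append(CONTINUOUS)
        names.append(f"inf{j}")
    for j in range(spec.n_noise_continuous):
        cols.append(rng.standard_normal(n))
        types.append(CONTINUOUS)
        names.append(f"noise{j}")
    # zero effect size means no class signal anywhere, discrete included
    p_mix = (_DISCRETE_P0 + _DISCRETE_P1) / 2
    disc_p = {
        0: _DISCRETE_P0 if spec.effect_size > 0 else p_mix,
        1: _DISCRETE_P1 if spec.effect_size > 0 else p_mix,
    }
    for j in range(spec.n_discrete):
        draw = np.empty(n)
        for cls_code, p in disc_p.items():
            sel = y == cls_code
            draw[sel] = rng.choice(len(p), size=int(sel.sum()), p=p)
        cols.append(draw)
        types.append(DISCRETE)
        names.append(f"cat{j}")

    if not cols:
        raise DataError("spec generates no features")
    X = np.column_stack(cols)
    return Dataset(
        X=X,
        mask=np.zeros_like(X, dtype=bool),
        feature_types=types,
        y=y,
        feature_names=names,
        label_names=["neg", "pos"],
        name=spec.name,
    )


def true_boundaries(spec: SyntheticSpec) -> dict[str, float]:
    """Bayes-optimal cut per informative feature (midpoint of class means)."""
    return {f"inf{j}": b for j, b in enumerate(spec.boundary_locations)}


def known_cut_recovery_check(
    spec: SyntheticSpec, method: str, params=None
) -> dict[str, float]:
    """Distance from each informative feature's nearest fitted cut to truth.

    Fits the discretizer on one generated dataset; returns
    ``{feature: |nearest cut - true boundary|}``.  Features for which the
    discretizer accepted no cut map to ``inf`` so callers can count
    misses.  Returns an empty dict when no informative signal exists.
    """
    if spec.effect_size == 0 or spec.n_informative_continuous == 0:
        return {}
    d = generate(spec)
    scheme: CutoffScheme = fit_scheme(d, method, params)
    truth = true_boundaries(spec)
    errors: dict[str, float] = {}
    for name, b in truth.items():
        cuts = scheme.features[name].cuts
        errors[name] = min((abs(c - b) for c in cuts), default=float("inf"))
    return errors
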