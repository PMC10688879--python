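"""Supervised discretization: MDLP entropy splitting and ChiMerge merging.

Both methods are univariate and deterministic.  They produce a
:class:`CutoffScheme` — per continuous feature, an ordered list of real
cut points d_1 < ... < d_{k-1} defining k left-open right-closed intervals

    (-inf, d_1], (d_1, d_2], ..., (d_{k-1}, +inf)

so every real value, including unseen test values, maps to exactly one
interval code 0..k-1.

MDLP recursively splits at the class-boundary midpoint that minimises the
weighted child entropy, accepting a split only when its information gain
clears the minimum-description-length coding cost

    Gain(A,T;S) > log2(N-1)/N + Delta(A,T;S)/N,
    Delta = log2(3^c - 2) - [c*Ent(S) - c1*Ent(S1) - c2*Ent(S2)],

with c, c1, c2 the number of distinct classes in the node and its two
children and all logarithms base 2.

ChiMerge starts from one interval per distinct value and repeatedly fuses
the adjacent pair with the smallest interval-by-class chi-square until
every adjacent pair differs at the configured significance level
(degrees of freedom = classes present in the pair minus one); an optional
interval cap forces further merging of the smallest-chi-square pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .data_model import CONTINUOUS, DISCRETE, DataError, Dataset

MDLP = "mdlp"
CHIMERGE = "chimerge"


@dataclass
class FeatureCuts:
    """Cut points for one feature.  k = len(cuts) + 1 intervals."""

    cuts: list[float]
    method: str
    fitted_on: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise DataError("cut points must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return len(self.cuts) + 1


@dataclass
class CutoffScheme:
    """Per-feature cut points keyed by feature name."""

    features: dict[str, FeatureCuts] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            name: {"method": fc.method, "cuts": fc.cuts, "fitted_on": fc.fitted_on}
            for name, fc in self.features.items()
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CutoffScheme":
        doc = json.loads(text)
        return cls(
            features={
                name: FeatureCuts(
                    cuts=[float(c) for c in e["cuts"]],
                    method=e["method"],
                    fitted_on=int(e.get("fitted_on", 0)),
                )
                for name, e in doc.items()
            }
        )


@dataclass
class ChiMergeParams:
    """ChiMerge configuration.

    significance : merge threshold alpha; adjacent intervals stay separate
        once their chi-square exceeds the (1-alpha) critical value.
    max_intervals : optional hard cap on the interval count.
    min_expected_adjust : if True, classes absent from both intervals of a
        pair are skipped in the chi-square sum (zero expected count).
    """

    significance: float = 0.05
    max_intervals: int | None = None
    min_expected_adjust: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.significance < 1:
            raise DataError("significance must lie in (0, 1)")
        if self.max_intervals is not None and self.max_intervals < 2:
            raise DataError("max_intervals must be at least 2")


# ---------------------------------------------------------------------------
# entropy helpers
# ---------------------------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (base 2) of a class-count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mdlp_accepts(total: np.ndarray, left: np.ndarray, right: np.ndarray) -> bool:
    """Fayyad–Irani acceptance test on class-count vectors."""
    n = int(total.sum())
    ent_s = _entropy(total)
    ent_1 = _entropy(left)
    ent_2 = _entropy(right)
    gain = ent_s - (left.sum() / n) * ent_1 - (right.sum() / n) * ent_2
    c = int((total > 0).sum())
    c1 = int((left > 0).sum())
    c2 = int((right > 0).sum())
    delta = math.log2(3**c - 2) - (c * ent_s - c1 * ent_1 - c2 * ent_2)
    return gain > math.log2(n - 1) / n + delta / n


def _class_counts(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(labels, minlength=n_classes)


# ---------------------------------------------------------------------------
# MDLP
# ---------------------------------------------------------------------------


def fit_mdlp(values, labels) -> FeatureCuts:
    """Fit MDLP cut points for a single continuous feature.

    ``values`` and ``labels`` must be equal-length with no missing entries.
    Returns a :class:`FeatureCuts`; a feature that admits no accepted cut
    has ``cuts == []``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.size == 0:
        raise DataError("cannot discretize an empty feature")
    if values.shape != labels.shape:
        raise DataError("values and labels must have the same length")
    if values.size < 2 or np.unique(values).size < 2:
        return FeatureCuts(cuts=[], method=MDLP, fitted_on=values.size)

    order = np.argsort(values, kind="stable")
    sv, sl = values[order], labels[order]
    n_classes = int(labels.max()) + 1

    # collapse equal values into blocks: no cut can separate ties
    uniq, start = np.unique(sv, return_index=True)
    block_counts = np.zeros((uniq.size, n_classes), dtype=int)
    bounds = np.append(start, sv.size)
    for b in range(uniq.size):
        block_counts[b] = _class_counts(sl[bounds[b] : bounds[b + 1]], n_classes)

    cuts: list[float] = []
    _mdlp_recurse(uniq, block_counts, cuts)
    cuts.sort()
    return FeatureCuts(cuts=cuts, method=MDLP, fitted_on=values.size)


def _boundary_candidates(counts: np.ndarray) -> np.ndarray:
    """Indices b where a cut between block b and b+1 is a class boundary.

    A boundary exists unless both adjacent blocks are pure in the same
    single class (cutting inside a run of one class can never minimise
    entropy strictly).
    """
    nb = counts.shape[0]
    cand = []
    for b in range(nb - 1):
        left, right = counts[b], counts[b + 1]
        lc = np.flatnonzero(left)
        rc = np.flatnonzero(right)
        if lc.size == 1 and rc.size == 1 and lc[0] == rc[0]:
            continue
        cand.append(b)
    return np.asarray(cand, dtype=int)


def _mdlp_recurse(uniq: np.ndarray, counts: np.ndarray, cuts: list[float]) -> None:
    if uniq.size < 2:
        return
    total = counts.sum(axis=0)
    if int((total > 0).sum()) < 2:
        return  # pure node
    n = int(total.sum())
    cand = _boundary_candidates(counts)
    if cand.size == 0:
        return
    cum = np.cumsum(counts, axis=0)
    best_b, best_ent = -1, np.inf
    for b in cand:
        left = cum[b]
        right = total - left
        ent = (left.sum() / n) * _entropy(left) + (right.sum() / n) * _entropy(right)
        if ent < best_ent:  # strict: leftmost candidate wins exact ties
            best_ent, best_b = ent, int(b)
    left = cum[best_b]
    right = total - left
    if not _mdlp_accepts(total, left, right):
        return
    cuts.append(float((uniq[best_b] + uniq[best_b + 1]) / 2.0))
    _mdlp_recurse(uniq[: best_b + 1], counts[: best_b + 1], cuts)
    _mdlp_recurse(uniq[best_b + 1 :], counts[best_b + 1 :], cuts)


# ---------------------------------------------------------------------------
# ChiMerge
# ---------------------------------------------------------------------------


def pair_chi_square(left: np.ndarray, right: np.ndarray) -> float:
    """Chi-square of a 2 x C adjacent-interval contingency table.

    Classes absent from both rows contribute nothing (their expected
    count is zero and the term is skipped).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    col = left + right
    present = col > 0
    if not present.any():
        return 0.0
    nl, nr = left.sum(), right.sum()
    total = nl + nr
    e_left = nl * col[present] / total
    e_right = nr * col[present] / total
    chi = 0.0
    for o, e in ((left[present], e_left), (right[present], e_right)):
        nz = e > 0
        chi += float(((o[nz] - e[nz]) ** 2 / e[nz]).sum())
    return chi


def _pair_df(left: np.ndarray, right: np.ndarray) -> int:
    present = int(((left + right) > 0).sum())
    return max(present - 1, 1)


def fit_chimerge(values, labels, params: ChiMergeParams | None = None) -> FeatureCuts:
    """Fit ChiMerge cut points for a single continuous feature."""
    params = params or ChiMergeParams()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.size == 0:
        raise DataError("cannot discretize an empty feature")
    if values.shape != labels.shape:
        raise DataError("values and labels must have the same length")
    if values.size < 2 or np.unique(values).size < 2:
        return FeatureCuts(cuts=[], method=CHIMERGE, fitted_on=values.size)

    order = np.argsort(values, kind="stable")
    sv, sl = values[order], labels[order]
    n_classes = int(labels.max()) + 1

    uniq, start = np.unique(sv, return_index=True)
    bounds = np.append(start, sv.size)
    counts = [
        _class_counts(sl[bounds[b] : bounds[b + 1]], n_classes) for b in range(uniq.size)
    ]
    # interval b spans values in [lo[b], hi[b]]
    lo = list(uniq)
    hi = list(uniq)

    def merge_until(stop_fn) -> None:
        chis = [pair_chi_square(counts[i], counts[i + 1]) for i in range(len(counts) - 1)]
        while chis and not stop_fn(chis):
            i = int(np.argmin(chis))  # leftmost minimum
            counts[i] = counts[i] + counts[i + 1]
            del counts[i + 1]
            hi[i] = hi[i + 1]
            del lo[i + 1], hi[i + 1]
            del chis[i]
            if i > 0:
                chis[i - 1] = pair_chi_square(counts[i - 1], counts[i])
            if i < len(chis):
                chis[i] = pair_chi_square(counts[i], counts[i + 1])

    def significant(chis) -> bool:
        for i, chi in enumerate(chis):
            df = _pair_df(counts[i], counts[i + 1])
            crit = chi2_dist.ppf(1.0 - params.significance, df)
            if chi <= crit:
                return False
        return True

    merge_until(significant)
    if params.max_intervals is not None:
        merge_until(lambda chis: len(counts) <= params.max_intervals)

    cuts = [float((hi[i] + lo[i + 1]) / 2.0) for i in range(len(counts) - 1)]
    return FeatureCuts(cuts=cuts, method=CHIMERGE, fitted_on=values.size)


# ---------------------------------------------------------------------------
# dataset-level fit / apply
# ---------------------------------------------------------------------------


def fit_scheme(d: Dataset, method: str, params=None) -> CutoffScheme:
    """Fit the chosen discretizer independently on every continuous feature.

    Discrete features pass through untouched.  ``d`` must be complete in
    its continuous features.
    """
    d.require_supervised()
    scheme = CutoffScheme()
    for j in d.continuous_indices:
        if d.mask[:, j].any():
            raise DataError(
                f"feature {d.feature_names[j]!r} has missing values; "
                "fit the scheme on the complete subset"
            )
        if method == MDLP:
            fc = fit_mdlp(d.X[:, j], d.y)
        elif method == CHIMERGE:
            fc = fit_chimerge(d.X[:, j], d.y, params)
        else:
            raise DataError(f"unknown discretization method {method!r}")
        scheme.features[d.feature_names[j]] = fc
    return scheme


def apply_scheme(d: Dataset, scheme: CutoffScheme) -> Dataset:
    """Map continuous values to interval codes; missing cells stay missing.

    Value v gets code i with d_i < v <= d_{i+1} under the left-open
    right-closed convention; the extreme intervals are unbounded, so any
    real value is assigned.  Transformed features are re-tagged discrete.
    """
    out = d.copy()
    for j in d.continuous_indices:
        name = d.feature_names[j]
        if name not in scheme.features:
            raise DataError(f"scheme has no cuts for continuous feature {name!r}")
        cuts = np.asarray(scheme.features[name].cuts, dtype=float)
        obs = ~d.mask[:, j]
        # side='left' makes the intervals right-closed: v == d_i -> code i-1
        codes = np.searchsorted(cuts, d.X[obs, j], side="left")
        out.X[obs, j] = codes.astype(float)
        out.feature_types[j] = DISCRETE
    return out
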