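import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import discimpute as di
from discimpute.data_model import DataError
from discimpute.discretize import pair_chi_square

from .conftest import make_random_instance
from .oracles import mdlp_oracle


class TestMDLP:
    def test_worked_four_point_node(self):
        fc = di.fit_mdlp([1, 2, 3, 4], [0, 0, 1, 1])
        assert fc.cuts == [2.5]

    def test_single_class_no_cut(self):
        assert di.fit_mdlp([1.0, 2.0, 5.0, 9.0], [1, 1, 1, 1]).cuts == []

    def test_identical_values_no_cut(self):
        assert di.fit_mdlp([3.0] * 6, [0, 1, 0, 1, 0, 1]).cuts == []

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            di.fit_mdlp([], [])

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(250):
            values, labels = make_random_instance(rng)
            got = di.fit_mdlp(values, labels).cuts
            want = mdlp_oracle(values, labels)
            assert got == pytest.approx(want), (values.tolist(), labels.tolist())

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=60)
        labels = (values + rng.normal(scale=0.3, size=60) > 0).astype(int)
        base = di.fit_mdlp(values, labels).cuts
        perm = rng.permutation(60)
        assert di.fit_mdlp(values[perm], labels[perm]).cuts == base

    def test_monotone_transform_preserves_assignments(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=80)
        labels = (values > 0.2).astype(int)
        fc = di.fit_mdlp(values, labels)
        fc_t = di.fit_mdlp(np.exp(values), labels)
        codes = np.searchsorted(fc.cuts, values, side="left")
        codes_t = np.searchsorted(fc_t.cuts, np.exp(values), side="left")
        assert np.array_equal(codes, codes_t)


class TestChiMerge:
    def test_pure_pair_chi_square_closed_form(self):
        assert pair_chi_square(np.array([10, 0]), np.array([0, 10])) == 20.0

    def test_absent_class_skipped(self):
        # third class absent from both rows: identical to the 2-class table
        a = pair_chi_square(np.array([4, 1, 0]), np.array([1, 4, 0]))
        b = pair_chi_square(np.array([4, 1]), np.array([1, 4]))
        assert a == pytest.approx(b)

    def test_two_block_fixture_single_cut(self):
        fc = di.fit_chimerge(range(1, 9), [0, 0, 0, 0, 1, 1, 1, 1],
                             di.ChiMergeParams(significance=0.05))
        assert fc.cuts == [4.5]

    def test_single_class_merges_everything(self):
        assert di.fit_chimerge([1, 2, 3, 4, 5], [0] * 5).cuts == []

    def test_significance_monotonicity(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=120)
        labels = (values + rng.normal(scale=0.8, size=120) > 0).astype(int)
        ks = []
        for alpha in (0.5, 0.1, 0.05, 0.01, 0.001):
            fc = di.fit_chimerge(values, labels, di.ChiMergeParams(significance=alpha))
            ks.append(fc.n_intervals)
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_max_intervals_cap_enforced(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=200)
        labels = rng.integers(0, 3, size=200)
        fc = di.fit_chimerge(values, labels,
                             di.ChiMergeParams(significance=0.9, max_intervals=4))
        assert fc.n_intervals <= 4

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=70)
        labels = (values > 0).astype(int)
        base = di.fit_chimerge(values, labels).cuts
        perm = rng.permutation(70)
        assert di.fit_chimerge(values[perm], labels[perm]).cuts == base


class TestSchemeFitApply:
    def test_fit_covers_continuous_only(self, toy_mixed):
        scheme = di.fit_scheme(toy_mixed, di.MDLP)
        assert set(scheme.features) == {"a", "b"}

    def test_scheme_invariant_to_record_order(self, toy_mixed):
        base = di.fit_scheme(toy_mixed, di.MDLP)
        shuffled = toy_mixed.take(np.random.default_rng(0).permutation(8))
        again = di.fit_scheme(shuffled, di.MDLP)
        for name in base.features:
            assert base.features[name].cuts == again.features[name].cuts

    @pytest.mark.parametrize("value,code", [
        (-5.0, 0), (2.5, 0), (2.5000001, 1),
    ])
    def test_boundary_convention_right_closed(self, value, code):
        scheme = di.CutoffScheme(features={
            "a": di.FeatureCuts(cuts=[2.5], method=di.MDLP)})
        X = np.array([[value]])
        d = di.Dataset(X=X, mask=np.zeros_like(X, bool),
                       feature_types=[di.CONTINUOUS], y=np.array([0]),
                       feature_names=["a"])
        out = di.apply_scheme(d, scheme)
        assert out.X[0, 0] == code and out.feature_types == [di.DISCRETE]

    def test_multi_cut_interval_codes(self):
        scheme = di.CutoffScheme(features={
            "a": di.FeatureCuts(cuts=[10.0, 20.0], method=di.MDLP)})
        X = np.array([[-5.0], [10.0], [15.0], [99.0]])
        d = di.Dataset(X=X, mask=np.zeros_like(X, bool),
                       feature_types=[di.CONTINUOUS], y=np.array([0, 1, 0, 1]),
                       feature_names=["a"])
        assert di.apply_scheme(d, scheme).X[:, 0].tolist() == [0, 0, 1, 2]

    def test_empty_cuts_single_interval(self):
        scheme = di.CutoffScheme(features={
            "a": di.FeatureCuts(cuts=[], method=di.MDLP)})
        X = np.array([[-1e9], [0.0], [1e9]])
        d = di.Dataset(X=X, mask=np.zeros_like(X, bool),
                       feature_types=[di.CONTINUOUS], y=np.array([0, 1, 0]),
                       feature_names=["a"])
        assert di.apply_scheme(d, scheme).X[:, 0].tolist() == [0, 0, 0]

    def test_missing_cells_stay_missing(self, toy_masked):
        comp, _ = di.split_complete_incomplete(toy_masked)
        scheme = di.fit_scheme(comp, di.CHIMERGE)
        out = di.apply_scheme(toy_masked, scheme)
        assert np.array_equal(out.mask, toy_masked.mask)

    def test_json_round_trip_exact(self):
        scheme = di.CutoffScheme(features={
            "a": di.FeatureCuts(cuts=[0.1, 0.30000000000000004], method=di.MDLP,
                                fitted_on=12),
            "b": di.FeatureCuts(cuts=[], method=di.CHIMERGE, fitted_on=12),
        })
        back = di.CutoffScheme.from_json(scheme.to_json())
        for name in scheme.features:
            assert back.features[name].cuts == scheme.features[name].cuts
            assert back.features[name].method == scheme.features[name].method

    def test_strictly_increasing_cuts_enforced(self):
        with pytest.raises(DataError):
            di.FeatureCuts(cuts=[2.0, 1.0], method=di.MDLP)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 6), min_size=2, max_size=20),
       st.lists(st.integers(0, 2), min_size=2, max_size=20))
def test_mdlp_oracle_property(vals, labs):
    """Recursive fitter and exhaustive oracle agree on arbitrary small input."""
    n = min(len(vals), len(labs))
    values = np.array(vals[:n], dtype=float)
    labels = np.array(labs[:n])
    assert di.fit_mdlp(values, labels).cuts == pytest.approx(mdlp_oracle(values, labels))
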