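import numpy as np
import pytest

import discimpute as di
from discimpute.data_model import DataError

from .oracles import knn_impute_oracle


def make_dataset(X, types, y=None, mask=None):
    X = np.asarray(X, float)
    return di.Dataset(
        X=X,
        mask=np.zeros_like(X, bool) if mask is None else np.asarray(mask, bool),
        feature_types=list(types),
        y=np.zeros(len(X), int) if y is None else np.asarray(y, int),
    )


class TestMeanMode:
    def test_column_statistics(self):
        d = make_dataset([[1, 0], [2, 0], [3, 1]],
                         [di.CONTINUOUS, di.DISCRETE], y=[0, 1, 0])
        m = di.fit_imputer(d, di.MEAN_MODE)
        assert m.statistics[0] == pytest.approx(2.0)
        assert m.statistics[1] == 0  # mode

    def test_mode_tie_smallest_code(self):
        d = make_dataset([[0], [1], [0], [1]], [di.DISCRETE])
        m = di.fit_imputer(d, di.MEAN_MODE)
        assert m.statistics[0] == 0

    def test_record_completion_preserves_observed(self):
        d = make_dataset([[1, 5], [2, 6], [3, 7]],
                         [di.CONTINUOUS, di.CONTINUOUS])
        m = di.fit_imputer(d, di.MEAN_MODE)
        out = di.impute_record(m, np.array([9.0, 0.0]), np.array([True, False]))
        assert out[0] == 9.0 and out[1] == pytest.approx(6.0)

    def test_all_missing_record_still_succeeds(self):
        d = make_dataset([[1, 5], [3, 7]], [di.CONTINUOUS, di.CONTINUOUS])
        m = di.fit_imputer(d, di.MEAN_MODE)
        out = di.impute_record(m, np.zeros(2), np.array([False, False]))
        assert out.tolist() == [2.0, 6.0]


class TestKNN:
    def test_exact_duplicate_dominates_k1(self):
        d = make_dataset([[1, 10], [2, 20], [3, 30]],
                         [di.CONTINUOUS, di.CONTINUOUS])
        m = di.fit_imputer(d, di.KNN, k=1)
        out = di.impute_record(m, np.array([2.0, 0.0]), np.array([True, False]))
        assert out[1] == 20.0

    def test_all_missing_rejected(self):
        d = make_dataset([[1, 2]] * 3, [di.CONTINUOUS, di.CONTINUOUS])
        m = di.fit_imputer(d, di.KNN, k=2)
        with pytest.raises(DataError, match="observed"):
            di.impute_record(m, np.zeros(2), np.array([False, False]))

    def test_k_exceeding_records_rejected(self):
        d = make_dataset([[1, 2]] * 3, [di.CONTINUOUS, di.CONTINUOUS])
        with pytest.raises(DataError, match="k="):
            di.fit_imputer(d, di.KNN, k=4)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(120):
            n = int(rng.integers(5, 51))
            m_feats = int(rng.integers(2, 6))
            types = [di.CONTINUOUS if rng.random() < 0.6 else di.DISCRETE
                     for _ in range(m_feats)]
            X = np.column_stack([
                rng.normal(size=n) if t == di.CONTINUOUS
                else rng.integers(0, 3, size=n).astype(float)
                for t in types
            ])
            d = make_dataset(X, types)
            k = int(rng.integers(1, min(n, 7) + 1))
            model = di.fit_imputer(d, di.KNN, k=k)
            query = X[rng.integers(n)].copy() + rng.normal(scale=0.1, size=m_feats)
            observed = rng.random(m_feats) < 0.7
            if not observed.any():
                observed[0] = True
            got = di.impute_record(model, query, observed)
            want = knn_impute_oracle(X, types, model.ranges, query, observed, k)
            assert got == pytest.approx(want)

    def test_discrete_vote_returns_existing_category(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=30),
                             rng.integers(0, 3, size=30).astype(float)])
        d = make_dataset(X, [di.CONTINUOUS, di.DISCRETE])
        m = di.fit_imputer(d, di.KNN, k=5)
        out = di.impute_record(m, np.array([0.0, 0.0]), np.array([True, False]))
        assert out[1] in {0.0, 1.0, 2.0}


class TestCART:
    def test_learns_deterministic_rule(self):
        rng = np.random.default_rng(8)
        f1 = rng.uniform(0, 10, size=200)
        f2 = (f1 > 5).astype(float)
        d = make_dataset(np.column_stack([f1, f2]),
                         [di.CONTINUOUS, di.DISCRETE])
        m = di.fit_imputer(d, di.CART, seed=0)
        preds = [di.impute_record(m, np.array([v, 0.0]),
                                  np.array([True, False]))[1]
                 for v in (1.0, 9.0)]
        assert preds == [0.0, 1.0]

    def test_error_shrinks_with_sample_size(self):
        # masked feature is an exact function of the others
        rng = np.random.default_rng(21)
        n = 500
        f1 = rng.uniform(-2, 2, size=n)
        f2 = rng.uniform(-2, 2, size=n)
        f3 = 2.0 * f1 - f2
        d = make_dataset(np.column_stack([f1, f2, f3]), [di.CONTINUOUS] * 3)
        m = di.fit_imputer(d, di.CART, seed=1)
        qx = rng.uniform(-1.5, 1.5, size=(100, 2))
        errs = []
        for a, b in qx:
            out = di.impute_record(m, np.array([a, b, 0.0]),
                                   np.array([True, True, False]))
            errs.append(abs(out[2] - (2 * a - b)))
        assert np.mean(errs) < 0.25

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        d = make_dataset(X, [di.CONTINUOUS] * 3)
        q = np.array([0.3, -0.2, 0.0])
        obs = np.array([True, True, False])
        a = di.impute_record(di.fit_imputer(d, di.CART, seed=7), q, obs)
        b = di.impute_record(di.fit_imputer(d, di.CART, seed=7), q, obs)
        assert a.tolist() == b.tolist()


class TestImputeDataset:
    @pytest.mark.parametrize("method", [di.MEAN_MODE, di.KNN, di.CART])
    def test_observed_cells_never_altered(self, method, toy_masked):
        comp, inc = di.split_complete_incomplete(toy_masked)
        m = di.fit_imputer(comp, method, k=3, seed=0)
        out = di.impute_dataset(m, inc)
        assert out.is_complete()
        obs = ~inc.mask
        assert np.array_equal(out.X[obs], inc.X[obs])

    def test_complete_input_is_identity(self, toy_mixed):
        m = di.fit_imputer(toy_mixed, di.MEAN_MODE)
        out = di.impute_dataset(m, toy_mixed)
        assert np.array_equal(out.X, toy_mixed.X)

    def test_records_imputed_independently_of_order(self, toy_masked):
        comp, inc = di.split_complete_incomplete(toy_masked)
        m = di.fit_imputer(comp, di.KNN, k=3)
        base = di.impute_dataset(m, inc)
        flipped = di.impute_dataset(m, inc.take(np.array([1, 0])))
        # same record (by id) gets the same imputed values either way
        for rid in inc.record_ids:
            i = list(base.record_ids).index(rid)
            j = list(flipped.record_ids).index(rid)
            assert base.X[i].tolist() == flipped.X[j].tolist()

    def test_empty_complete_set_rejected(self):
        d = make_dataset(np.zeros((0, 2)), [di.CONTINUOUS] * 2, y=[])
        with pytest.raises(DataError):
            di.fit_imputer(d, di.MEAN_MODE)
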