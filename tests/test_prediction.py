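"""LOO-CV symptom prediction with F-ranked feature selection."""

import numpy as np
import pytest
from sklearn.feature_selection import f_regression

from nspnet import (
    AtlasMap,
    PredictionModelSpec,
    f_rank,
    loo_cv_predict,
    permutation_pvalue,
    select_best_k,
    system_weights,
)


class TestFRank:
    def test_feature_equal_to_target_ranked_first(self, rng):
        X = rng.standard_normal((40, 8))
        y = X[:, 5].copy()
        order, _ = f_rank(X, y)
        assert order[0] == 5

    def test_f_monotone_in_abs_r(self, rng):
        n = 60
        y = rng.standard_normal(n)
        X = np.column_stack(
            [a * y + rng.standard_normal(n) for a in (0.1, 0.5, 1.0, 2.0)]
        )
        _, f = f_rank(X, y)
        r = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(4)])
        assert np.array_equal(np.argsort(f), np.argsort(np.abs(r)))

    def test_matches_sklearn_f_regression(self, rng):
        X = rng.standard_normal((50, 12))
        y = rng.standard_normal(50)
        _, f = f_rank(X, y)
        f_sk, _ = f_regression(X, y)
        assert np.allclose(f, f_sk, rtol=1e-8)

    def test_zero_variance_feature_ranked_last(self, rng):
        X = rng.standard_normal((30, 4))
        X[:, 1] = 2.0
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="zero-variance"):
            order, f = f_rank(X, y)
        assert order[-1] == 1 and f[1] == 0.0


def naive_loo_predictions(X, y, k, selection):
    """Plain-loop reference: explicit fold masks, full re-ranking and
    re-standardization per fold."""
    n = X.shape[0]
    if selection == "global":
        order, _ = f_rank(X, y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Xtr, ytr = X[mask], y[mask]
        if selection == "in-fold":
            order, _ = f_rank(Xtr, ytr)
        sel = order[:k]
        mu, sd = Xtr[:, sel].mean(axis=0), Xtr[:, sel].std(axis=0)
        sd[sd == 0] = 1.0
        A = np.column_stack([np.ones(n - 1), (Xtr[:, sel] - mu) / sd])
        beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        preds[i] = beta[0] + ((X[i, sel] - mu) / sd) @ beta[1:]
    return preds


class TestLooCv:
    @pytest.mark.parametrize("selection", ["in-fold", "global"])
    def test_matches_naive_reference(self, rng, selection):
        X = rng.standard_normal((30, 9))
        y = X[:, 2] - 0.5 * X[:, 6] + rng.standard_normal(30)
        res = loo_cv_predict(X, y, PredictionModelSpec(k=4, selection=selection))
        ref = naive_loo_predictions(X, y, 4, selection)
        assert np.allclose(res.predicted, ref, atol=1e-9)

    def test_noiseless_linear_recovery(self, rng):
        """With every true feature available to the model, a noiseless
        linear target is recovered essentially exactly out-of-fold."""
        n, p = 40, 10
        X = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        y = X @ beta + 10.0
        res = loo_cv_predict(X, y, PredictionModelSpec(k=p))
        assert res.accuracy_r >= 0.999
        assert res.predicted.shape == (n,)

    def test_dominant_feature_found_in_fold(self, rng):
        """In-fold selection at K=1 locks onto a strongly dominant feature."""
        n, p = 60, 12
        X = rng.standard_normal((n, p))
        y = 5.0 * X[:, 4] + 0.3 * rng.standard_normal(n)
        res = loo_cv_predict(X, y, PredictionModelSpec(k=1))
        assert res.accuracy_r >= 0.99
        assert res.selected[0] == 4

    def test_permuted_target_accuracy_centered_near_zero(self):
        """Null accuracies scatter around zero (slightly negative: the
        held-out subject's score is absent from the training mean, the
        usual leave-one-out anticorrelation artifact)."""
        accs = []
        for seed in range(40):
            g = np.random.default_rng(seed)
            X = g.standard_normal((50, 10))
            y = g.permutation(X @ np.ones(10) + g.standard_normal(50))
            accs.append(loo_cv_predict(X, y, PredictionModelSpec(k=3)).accuracy_r)
        accs = np.array(accs)
        assert -0.2 < accs.mean() < 0.1
        assert (accs <= 0.5).all()

    def test_k_out_of_range_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError):
            loo_cv_predict(X, X[:, 0], PredictionModelSpec(k=6))

    def test_in_fold_selection_ignores_held_out_subject(self, rng):
        """Changing only the held-out subject's feature values must not
        change its standardized prediction inputs' training statistics:
        the prediction for every *other* subject stays identical."""
        X = rng.standard_normal((25, 8))
        y = X[:, 0] + 0.5 * rng.standard_normal(25)
        spec = PredictionModelSpec(k=3, selection="in-fold")
        base = loo_cv_predict(X, y, spec).predicted
        X2 = X.copy()
        X2[7] += 100.0  # corrupt one subject's features only
        pert = loo_cv_predict(X2, y, spec).predicted
        mask = np.arange(25) != 7
        # other folds trained without subject 7's y but WITH its features:
        # they shift; only the fold holding out subject 7 trains on clean data.
        # The leakage check is the converse: subject 7's own fold must be
        # identical because its training data excludes subject 7 entirely.
        assert not np.allclose(base[mask], pert[mask])  # features do enter others
        # train fold for subject 7 identical -> same ranking/scaling/weights,
        # but its own prediction uses its (corrupted) features; re-run with
        # corrupted y instead to isolate selection:
        y3 = y.copy()
        y3[7] += 100.0
        pert_y = loo_cv_predict(X, y3, spec).predicted
        assert np.allclose(base[7], pert_y[7])  # held-out y never used


class TestSelectBestK:
    def test_recovers_planted_support_size(self, rng):
        n, p = 60, 15
        X = rng.standard_normal((n, p))
        y = X[:, :5] @ np.array([3.0, 3.0, 2.5, 2.0, 2.0])
        y = y + 0.2 * rng.standard_normal(n)
        res = select_best_k(X, y, PredictionModelSpec())
        assert 3 <= res.k <= 8
        assert res.accuracy_r > 0.95

    def test_deterministic(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        a = select_best_k(X, y, PredictionModelSpec())
        b = select_best_k(X, y, PredictionModelSpec())
        assert a.k == b.k and a.accuracy_r == b.accuracy_r


class TestPermutationP:
    def test_strong_signal_hits_floor(self, rng):
        X = rng.standard_normal((30, 6))
        y = X[:, 0] * 3.0
        spec = PredictionModelSpec(k=2)
        obs = loo_cv_predict(X, y, spec).accuracy_r
        p = permutation_pvalue(X, y, spec, obs, n_perm=199, rng=1)
        assert p == pytest.approx(1 / 200)

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        spec = PredictionModelSpec(k=2)
        obs = loo_cv_predict(X, y, spec).accuracy_r
        a = permutation_pvalue(X, y, spec, obs, n_perm=50, rng=9)
        b = permutation_pvalue(X, y, spec, obs, n_perm=50, rng=9)
        assert a == b


class TestSystemWeights:
    def test_sums_and_single_system_support(self, rng):
        atlas = AtlasMap.evenly_split(14)
        w = np.zeros(14)
        vis = atlas.indices("VIS")
        w[vis] = [2.0, -0.5]
        sw = system_weights(w, atlas)
        assert sw["VIS"] == pytest.approx(1.5)
        assert all(v == 0.0 for k, v in sw.items() if k != "VIS")
        assert sum(sw.values()) == pytest.approx(w.sum())
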