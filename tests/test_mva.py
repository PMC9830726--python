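"""PLS/OPLS-DA against independent linear-algebra oracles, VIP, and Q2."""

import numpy as np
import pandas as pd
import pytest

from metabshape import (
    cross_validate, fit_oplsda, fit_plsda, permutation_q2, vip,
)
from metabshape.mva import _dummy_code, _stratified_folds

from oracles import svd_pls, vip_formula


def _two_class(n=24, p=10, gap=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    X[:, 0] += np.where(y == "B", gap, 0.0)
    return X, y


def _match_up_to_sign(A, B, tol):
    assert A.shape == B.shape
    for a in range(A.shape[1]):
        d = min(np.max(np.abs(A[:, a] - B[:, a])),
                np.max(np.abs(A[:, a] + B[:, a])))
        assert d <= tol, f"component {a}: {d}"


class TestPlsda:
    def test_perfect_predictor_r2y_one(self):
        y = np.array(["A"] * 10 + ["B"] * 10)
        X = (y == "B").astype(float)[:, None]  # X is exactly the dummy code
        m = fit_plsda(X, y, 1, scale="none")
        assert m.r2y[-1] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("shape", [(10, 6), (20, 50)])
    def test_nipals_matches_svd_oracle(self, seed, shape):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal(shape)
        y = np.array(["A", "B", "C"] * (shape[0] // 3) + ["A"] * (shape[0] % 3))
        m = fit_plsda(X, y, 3, scale="none")
        Y, _ = _dummy_code(y)
        T, _, _ = svd_pls(X.copy(), Y, 3)
        _match_up_to_sign(m.scores, T, 1e-8)

    def test_fixture_matrix_scores(self):
        # frozen 4x3 toy matrix, checked against the eigen-decomposition route
        X = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 1.5],
                      [3.0, 5.0, 2.0], [4.0, 4.0, 4.0]])
        y = np.array(["A", "A", "B", "B"])
        m = fit_plsda(X, y, 2, scale="none")
        Y, _ = _dummy_code(y)
        T, _, _ = svd_pls(X.copy(), Y, 2)
        _match_up_to_sign(m.scores, T, 1e-8)

    def test_matches_sklearn_pls(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _two_class(n=20, p=8, gap=2.0, seed=5)
        ybin = (y == "B").astype(float)
        m = fit_plsda(X, ybin, 2, scale="none")
        sk = sklearn_pls.PLSRegression(n_components=2, scale=False).fit(X, ybin)
        _match_up_to_sign(m.scores, sk.x_scores_, 1e-6)

    def test_pure_noise_overfits_training_but_not_cv(self):
        r2s, q2s = [], []
        for seed in range(50):
            X, y = _two_class(n=20, p=50, gap=0.0, seed=seed)
            r2y, q2 = cross_validate(
                X, y, {"kind": "plsda", "n_components": 2}, k_folds=5, seed=seed
            )
            r2s.append(r2y)
            q2s.append(q2)
        assert np.mean(r2s) > 0.5          # training fit looks impressive
        assert np.mean(q2s) <= 0.2         # cross-validation is not fooled

    def test_rank_and_level_errors(self):
        X, y = _two_class(n=6, p=3)
        with pytest.raises(ValueError, match="rank"):
            fit_plsda(X, y, 5)
        with pytest.raises(ValueError, match="2 levels"):
            fit_plsda(X, np.repeat("A", 6), 1)

    def test_deterministic_refit(self):
        X, y = _two_class(n=18, p=12, gap=1.0, seed=7)
        m1 = fit_plsda(X, y, 2)
        m2 = fit_plsda(X, y, 2)
        assert np.array_equal(m1.scores, m2.scores)
        assert np.array_equal(m1.weights, m2.weights)


class TestOplsda:
    def test_zero_orth_degenerates_to_pls1(self):
        X, y = _two_class(n=20, p=15, gap=1.5, seed=3)
        o = fit_oplsda(X, y, n_orth=0, scale="none")
        ybin = (y == "B").astype(float)
        Xc = X - X.mean(axis=0)
        w = Xc.T @ (ybin - ybin.mean())
        w /= np.linalg.norm(w)
        t = Xc @ w
        d = min(np.max(np.abs(o.t_pred - t)), np.max(np.abs(o.t_pred + t)))
        assert d <= 1e-8

    def test_orthogonal_direction_removed(self):
        # plant a strong structured direction orthogonal to the class contrast
        rng = np.random.default_rng(11)
        n, p = 40, 30
        y = np.array(["A"] * 20 + ["B"] * 20)
        ycode = (y == "B").astype(float)
        ortho = rng.standard_normal(n)
        ortho -= ortho @ (ycode - ycode.mean()) / np.sum(
            (ycode - ycode.mean()) ** 2) * (ycode - ycode.mean())
        direction = rng.standard_normal(p)
        X = rng.standard_normal((n, p)) + 5 * np.outer(ortho, direction)
        X[:, 0] += np.where(y == "B", 2.0, 0.0)
        m = fit_oplsda(X, y, n_orth=1, scale="none")
        r = np.corrcoef(m.t_pred, ortho)[0, 1]
        assert abs(r) < 0.05

    def test_separated_groups_high_r2y(self):
        # clouds at -5 sigma and +5 sigma on one variable
        X, y = _two_class(n=30, p=10, gap=10.0, seed=13)
        m = fit_oplsda(X, y, n_orth=1, scale="none")
        assert m.r2y > 0.95

    def test_score_orthogonality_invariant(self):
        X, y = _two_class(n=26, p=40, gap=1.0, seed=17)
        m = fit_oplsda(X, y, n_orth=3)
        for k in range(m.n_orth):
            assert abs(m.t_pred @ m.t_orth[:, k]) < 1e-8

    def test_non_binary_rejected(self):
        X = np.random.default_rng(0).standard_normal((9, 4))
        with pytest.raises(ValueError, match="binary"):
            fit_oplsda(X, np.array(["A", "B", "C"] * 3))


class TestVip:
    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(0)
        y = np.array(["A"] * 8 + ["B"] * 8)
        X = (y == "B").astype(float)[:, None] + 0.1 * rng.standard_normal((16, 1))
        m = fit_oplsda(X, y)
        assert vip(m).iloc[0] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("variant", ["pred", "total"])
    def test_normalization_identity(self, variant):
        X, y = _two_class(n=30, p=200, gap=1.0, seed=19)
        m = fit_oplsda(X, y, n_orth=2)
        v = vip(m, variant=variant)
        assert float((v**2).sum()) == pytest.approx(200, abs=1e-6)

    def test_plsda_vip_matches_direct_formula(self):
        # 6x4 fixture: independent spreadsheet-style evaluation from the
        # stored weights and per-component explained Y sums of squares
        X = np.array([
            [1.0, 0.2, 3.0, 0.4], [2.0, 1.2, 2.5, 0.1], [1.5, 0.8, 2.8, 0.9],
            [4.0, 3.1, 1.0, 2.0], [3.6, 2.9, 1.2, 2.2], [4.2, 3.3, 0.8, 1.7],
        ])
        y = np.array(["A", "A", "A", "B", "B", "B"])
        m = fit_plsda(X, y, 2)
        expected = vip_formula(m.weights, np.asarray(m.ssy_explained))
        assert np.allclose(vip(m).to_numpy(), expected, atol=1e-10)

    def test_feature_names_carried_from_dataframe(self):
        X, y = _two_class(n=12, p=3, gap=1.0)
        df = pd.DataFrame(X, columns=["alanine", "serine", "choline"])
        v = vip(fit_oplsda(df, y))
        assert list(v.index) == ["alanine", "serine", "choline"]


class TestCrossValidation:
    def test_separable_data_high_q2(self):
        # two clouds with a +-5 sigma gap are all but perfectly predictable
        X, y = _two_class(n=28, p=10, gap=10.0, seed=23)
        _, q2 = cross_validate(X, y, {"kind": "oplsda", "n_orth": 1, "scale": "none"}, 7, 0)
        assert q2 > 0.9

    def test_loo_matches_explicit_loop(self):
        X, y = _two_class(n=14, p=6, gap=1.5, seed=29)
        ycode = (y == "B").astype(float)
        _, q2 = cross_validate(X, y, {"kind": "oplsda", "n_orth": 1},
                               k_folds=14, seed=0)
        press = 0.0
        for i in range(14):
            mask = np.arange(14) != i
            m = fit_oplsda(X[mask], y[mask], n_orth=1)
            press += float((ycode[i] - m.predict(X[i][None, :])[0]) ** 2)
        q2_loo = 1.0 - press / float(np.sum((ycode - ycode.mean()) ** 2))
        assert q2 == pytest.approx(q2_loo, abs=1e-10)

    def test_permuted_labels_mean_q2_nonpositive(self):
        X, y = _two_class(n=24, p=40, gap=0.0, seed=31)
        q2s = permutation_q2(X, y, {"kind": "oplsda", "n_orth": 1},
                             n_perm=30, k_folds=6, seed=0)
        assert np.mean(q2s) <= 0

    def test_q2_below_r2y_on_random_fixtures(self):
        # known pathological exceptions are rare; allow one in fifty
        bad = 0
        for seed in range(50):
            X, y = _two_class(n=16, p=12, gap=0.8, seed=seed)
            r2y, q2 = cross_validate(X, y, {"kind": "oplsda", "n_orth": 1},
                                     k_folds=4, seed=seed)
            bad += q2 > r2y
        assert bad <= 1

    def test_fold_assignment_stratified_and_deterministic(self):
        y = np.array(["A"] * 9 + ["B"] * 12)
        f1 = _stratified_folds(y, 3, seed=7)
        f2 = _stratified_folds(y, 3, seed=7)
        assert np.array_equal(f1, f2)
        for fold in range(3):
            assert (f1[:9] == fold).sum() == 3
            assert (f1[9:] == fold).sum() == 4

    def test_bad_k_rejected(self):
        X, y = _two_class(n=10, p=4)
        with pytest.raises(ValueError, match="k_folds"):
            cross_validate(X, y, None, k_folds=1)
        with pytest.raises(ValueError, match="k_folds"):
            cross_validate(X, y, None, k_folds=11)
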