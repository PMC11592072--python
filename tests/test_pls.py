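"""NIPALS PLS1: oracle equivalence, closed forms, VIP identities, diagnostics.

The reference oracle below is a deliberately naive, loop-based NIPALS
implementation kept independent of the package's vectorized path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabopls import PLSDA, ModelError, PLSDAResults, fit_pls1


def oracle_nipals_pls1(X, y, A):
    """Textbook NIPALS PLS1, scalar loops, no sign convention."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    yc = y - y.mean()
    n, p = X.shape
    W, T, P, q = [], [], [], []
    for _ in range(A):
        w = np.zeros(p)
        for j in range(p):
            for i in range(n):
                w[j] += X[i, j] * yc[i]
        w = w / np.sqrt((w**2).sum())
        t = np.array([sum(X[i, j] * w[j] for j in range(p)) for i in range(n)])
        tt = (t**2).sum()
        qa = (yc * t).sum() / tt
        pv = np.array([sum(X[i, j] * t[i] for i in range(n)) / tt for j in range(p)])
        X = X - np.outer(t, pv)
        W.append(w), T.append(t), P.append(pv), q.append(qa)
    W, T, P, q = np.array(W).T, np.array(T).T, np.array(P).T, np.array(q)
    b = W @ np.linalg.solve(P.T @ W, q)
    return {"W": W, "T": T, "P": P, "q": q, "b": b, "y_mean": y.mean()}


def random_fixture(rng, n=12, p=6):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = np.zeros(n)
    y[rng.choice(n, n // 2, replace=False)] = 1.0
    return X, y


class TestOracleEquivalence:
    def test_matches_independent_oracle_on_random_fixtures(self, rng):
        """Predictions and coefficients agree with the loop-based oracle to
        1e-8 on 20 random 12 x 6 fixtures, 3 components."""
        for _ in range(20):
            X, y = random_fixture(rng)
            res = fit_pls1(X, y, 3)
            ref = oracle_nipals_pls1(X, y, 3)
            assert np.allclose(res.coefficients, ref["b"], atol=1e-8)
            assert np.allclose(
                res.predict(X), X @ ref["b"] + ref["y_mean"], atol=1e-8
            )
            # weights agree up to the sign convention
            assert np.allclose(np.abs(res.weights), np.abs(ref["W"]), atol=1e-8)

    def test_first_weight_is_normalized_covariance(self, rng):
        X, y = random_fixture(rng)
        res = fit_pls1(X, y, 2)
        w_direct = X.T @ (y - y.mean())
        w_direct /= np.linalg.norm(w_direct)
        if w_direct[np.argmax(np.abs(w_direct))] < 0:
            w_direct = -w_direct
        assert np.allclose(res.weights[:, 0], w_direct, atol=1e-12)

    def test_agrees_with_sklearn_pls_regression(self, rng):
        """Cross-check fitted values against scikit-learn's PLS (an
        independent implementation of the same algorithm)."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        for _ in range(5):
            X, y = random_fixture(rng, n=14, p=5)
            res = fit_pls1(X, y, 3)
            ref = sklearn_pls.PLSRegression(n_components=3, scale=False).fit(X, y)
            assert np.allclose(
                res.predict(X), ref.predict(X).ravel(), atol=1e-8
            )


class TestClosedForms:
    def test_perfect_single_predictor(self):
        """X equal to centered y reproduces y exactly; R2Y = 1; the
        coefficient equals the OLS slope on the scaled data."""
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        x = (y - y.mean()).reshape(-1, 1)
        res = fit_pls1(x, y, 1)
        assert np.allclose(res.fitted_values, y, atol=1e-12)
        assert res.r2y == pytest.approx(1.0)
        ols = float(np.linalg.lstsq(x, y - y.mean(), rcond=None)[0][0])
        assert res.coefficients[0] == pytest.approx(ols, abs=1e-12)

    def test_one_component_coefficient_is_w_times_q(self, rng):
        X, y = random_fixture(rng)
        res = fit_pls1(X, y, 1)
        assert np.allclose(
            res.coefficients, res.weights[:, 0] * res.y_loadings[0], atol=1e-12
        )

    def test_prediction_of_zero_row_returns_y_mean(self, rng):
        X, y = random_fixture(rng)
        res = fit_pls1(X, y, 2)
        assert res.predict(np.zeros((1, X.shape[1])))[0] == pytest.approx(y.mean())

    def test_row_permutation_permutes_predictions(self, rng):
        X, y = random_fixture(rng)
        res = fit_pls1(X, y, 2)
        perm = rng.permutation(X.shape[0])
        assert np.allclose(res.predict(X[perm]), res.predict(X)[perm])

    def test_coefficient_path_equals_score_path(self, rng):
        """ŷ via b = W(P'W)^{-1}q equals ŷ accumulated through the
        deflation recursion, for every component count."""
        for _ in range(5):
            X, y = random_fixture(rng, n=15, p=7)
            for A in (1, 2, 4):
                res = fit_pls1(X, y, A)
                Xd = X.copy()
                yhat = np.full(X.shape[0], y.mean())
                for a in range(A):
                    t = Xd @ res.weights[:, a]
                    yhat += res.y_loadings[a] * t
                    Xd = Xd - np.outer(t, res.x_loadings[:, a])
                assert np.allclose(res.predict(X), yhat, atol=1e-10)


class TestVip:
    def test_equal_weights_give_unit_vips(self):
        """One component with equal |w_j| across p features -> VIP_j = 1."""
        y = np.array([0, 0, 1, 1], dtype=float)
        X = np.column_stack([(y - 0.5) * 2] * 3)  # identical informative cols
        res = fit_pls1(X, y, 1)
        assert np.allclose(res.vip(), np.ones(3), atol=1e-10)

    def test_single_active_feature_closed_form(self):
        """w = (1, 0) -> VIP = (sqrt(2), 0)."""
        y = np.array([0, 0, 1, 1], dtype=float)
        X = np.column_stack([(y - 0.5) * 2, [1, -1, -1, 1]])
        res = fit_pls1(X, y, 1)
        assert np.allclose(res.weights[:, 0], [1.0, 0.0], atol=1e-12)
        assert np.allclose(res.vip(), [np.sqrt(2), 0.0], atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_vip_squared_sums_to_feature_count(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_fixture(rng, n=10, p=5)
        res = fit_pls1(X, y, rng.integers(1, 4))
        assert np.sum(res.vip() ** 2) == pytest.approx(5.0, abs=1e-8)


class TestDiagnosticsAndInvariants:
    def test_unit_weights_and_orthogonal_scores(self, rng):
        for _ in range(10):
            X, y = random_fixture(rng, n=16, p=8)
            res = fit_pls1(X, y, 4)
            assert np.allclose(np.linalg.norm(res.weights, axis=0), 1, atol=1e-10)
            G = res.scores.T @ res.scores
            norms = np.sqrt(np.diag(G))
            off = G - np.diag(np.diag(G))
            assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))

    def test_full_rank_decomposition_explains_all_x_variance(self, rng):
        X, y = random_fixture(rng, n=8, p=6)
        res = fit_pls1(X, y, 6)
        assert res.cumulative_x_variance == pytest.approx(1.0, abs=1e-8)

    def test_r2y_nondecreasing_in_components(self, rng):
        for _ in range(5):
            X, y = random_fixture(rng, n=14, p=8)
            r2 = [fit_pls1(X, y, A).r2y for A in range(1, 6)]
            assert np.all(np.diff(r2) >= -1e-12)

    def test_sign_convention_largest_weight_positive(self, rng):
        X, y = random_fixture(rng)
        res = fit_pls1(X, y, 3)
        for a in range(3):
            w = res.weights[:, a]
            assert w[np.argmax(np.abs(w))] > 0

    def test_errors(self, rng):
        X, y = random_fixture(rng)
        with pytest.raises(ModelError, match="both classes"):
            PLSDA(X, np.zeros(len(y)))
        with pytest.raises(ModelError, match="achievable maximum"):
            fit_pls1(X, y, 50)
        with pytest.raises(ModelError, match=r"\{0,1\}"):
            PLSDA(X, y + 0.5)

    def test_rank_deficient_fit_reports_achievable_maximum(self):
        y = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        x = (y - y.mean()).reshape(-1, 1)
        X = np.column_stack([x, 2 * x, -x])  # rank 1
        with pytest.raises(ModelError, match="achievable maximum is 1"):
            fit_pls1(X, y, 2)

    def test_json_round_trip(self, rng, tmp_path):
        X, y = random_fixture(rng)
        res = fit_pls1(X, y, 2)
        path = tmp_path / "model.json"
        res.to_json(path)
        back = PLSDAResults.from_json(path)
        assert np.allclose(back.coefficients, res.coefficients)
        assert np.allclose(back.predict(X), res.predict(X))
        assert back.r2y == pytest.approx(res.r2y)

    def test_summary_mentions_components_and_r2(self, rng):
        X, y = random_fixture(rng)
        text = fit_pls1(X, y, 2).summary()
        assert "components: 2" in text and "R2Y" in text
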