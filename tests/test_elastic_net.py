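"""Elastic-net logistic solver: oracle equivalence, limits, and decisions."""

import numpy as np
import pytest
from scipy.optimize import minimize

from conceptbench import elastic_net as en
from conceptbench.elastic_net import ElasticNetConfig


def oracle_solve(X, y, lam, mix):
    """Independent convex-optimizer oracle.

    The L1 term is made smooth by the positive/negative split w = w+ - w-
    (each half bound to be non-negative), so L-BFGS-B applies directly.
    Returns the optimal objective value.
    """
    n, p = X.shape

    def f(params):
        w = params[:p] - params[p : 2 * p]
        b = params[-1]
        z = y * (X @ w + b)
        return (
            np.mean(np.logaddexp(0.0, -z))
            + lam * mix * (params[: 2 * p].sum())
            + 0.5 * lam * (1 - mix) * w @ w
        )

    res = minimize(
        f,
        np.zeros(2 * p + 1),
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p) + [(None, None)],
        options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.fun


def random_problem(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 21))
    p = int(rng.integers(2, 11))
    X = rng.normal(size=(n, p))
    n_pos = int(rng.integers(1, n))
    y = np.array([1.0] * n_pos + [-1.0] * (n - n_pos))
    lam = float(rng.uniform(0.01, 1.0))
    mix = float(rng.uniform(0.0, 1.0))
    return X, y, lam, mix


@pytest.mark.parametrize("seed", range(12))
def test_solver_matches_convex_oracle(seed):
    X, y, lam, mix = random_problem(seed)
    cfg = ElasticNetConfig(
        mix=mix, penalty=lam, standardize=False, tolerance=1e-13, max_iterations=20000
    )
    m = en.fit(X, y, cfg)
    ours = en.objective(X, y, m.weights, m.intercept, lam, mix)
    assert ours <= oracle_solve(X, y, lam, mix) + 1e-6


def test_ridge_matches_sklearn_saga():
    """Cross-check against an established solver with matched objective
    (sklearn uses a sum-loss parameterization: 1/C = n * lam)."""
    sklearn = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(5)
    X = rng.normal(size=(12, 4))
    y = np.array([1.0] * 6 + [-1.0] * 6)
    lam, mix = 0.2, 0.5
    sk = sklearn.LogisticRegression(
        penalty="elasticnet", l1_ratio=mix, C=1.0 / (len(y) * lam),
        solver="saga", tol=1e-10, max_iter=100000, fit_intercept=True,
    ).fit(X, y)
    sk_obj = en.objective(X, y, sk.coef_.ravel(), sk.intercept_[0], lam, mix)
    m = en.fit(X, y, ElasticNetConfig(mix=mix, penalty=lam, standardize=False,
                                      tolerance=1e-13, max_iterations=20000))
    ours = en.objective(X, y, m.weights, m.intercept, lam, mix)
    assert ours <= sk_obj + 1e-6


def test_huge_penalty_shrinks_to_null_model():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 5))
    y = np.array([1.0] * 5 + [-1.0] * 5)
    m = en.fit(X, y, ElasticNetConfig(penalty=1e6))
    assert np.allclose(m.weights, 0.0, atol=1e-8)
    assert m.intercept == pytest.approx(0.0, abs=1e-6)  # balanced log-odds


def test_two_point_separable_problem_stays_finite():
    # the n = 2 few-shot condition: one positive, one negative, separable
    X = np.array([[1.0, 0.0], [-1.0, 0.0]])
    y = np.array([1.0, -1.0])
    m = en.fit(X, y, ElasticNetConfig(penalty=0.5))
    assert np.isfinite(m.weights).all() and np.isfinite(m.intercept)
    obj = en.objective(X, y, m.weights, m.intercept, 0.5, 0.5)
    assert np.isfinite(obj)


@pytest.mark.parametrize("seed", range(6))
def test_objective_monotone_nonincreasing(seed):
    X, y, lam, mix = random_problem(seed + 100)
    m = en.fit(X, y, ElasticNetConfig(mix=mix, penalty=lam))
    hist = np.asarray(m.objective_history)
    assert np.all(np.diff(hist) <= 1e-12)


def test_lasso_single_feature_matches_grid_search():
    """With mix=1 and one standardized feature, the fitted weight matches a
    dense 1-D grid search over (w, b) to 1e-4."""
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    x = (x - x.mean()) / x.std()
    y = np.where(x + 0.3 * rng.normal(size=30) > 0, 1.0, -1.0)
    lam = 0.15
    X = x[:, None]
    m = en.fit(X, y, ElasticNetConfig(mix=1.0, penalty=lam, standardize=False,
                                      tolerance=1e-14, max_iterations=50000))
    def grid_min(w_lo, w_hi, b_lo, b_hi, steps=201):
        ws = np.linspace(w_lo, w_hi, steps)
        bs = np.linspace(b_lo, b_hi, steps)
        z = y[:, None, None] * (X @ ws[None, :] + 0)[:, :, None] + y[:, None, None] * bs
        obj = np.mean(np.logaddexp(0, -z), axis=0) + lam * np.abs(ws)[:, None]
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        return ws[i], bs[j], (ws[1] - ws[0]), (bs[1] - bs[0])

    w, b, dw, db = -0.0, 0.0, 3.0, 0.5
    for _ in range(5):  # successive refinement: dense grid search, zoomed in
        w, b, dw, db = grid_min(w - 2 * dw, w + 2 * dw, b - 2 * db, b + 2 * db)
    assert m.weights[0] == pytest.approx(w, abs=1e-4)


def test_decide_tie_is_negative():
    X = np.zeros((4, 3))
    y = np.array([1.0, 1.0, -1.0, -1.0])
    m = en.fit(X + np.eye(4, 3) * 1e-9, y, ElasticNetConfig(penalty=1e8))
    labels, scores = en.decide(m, np.zeros((2, 3)))
    assert np.allclose(scores, 0.5, atol=1e-6)
    assert not labels.any()  # exact/near ties at 0.5 fall to negative


def test_decide_monotone_in_positive_feature():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 4))
    y = np.where(X[:, 0] > 0, 1.0, -1.0)
    m = en.fit(X, y, ElasticNetConfig(penalty=0.05))
    j = int(np.argmax(m.weights))
    assert m.weights[j] > 0
    base = np.zeros((1, 4))
    scores = []
    for v in np.linspace(-2, 2, 9):
        probe = base.copy()
        probe[0, j] = v
        scores.append(en.decide(m, probe)[1][0])
    assert np.all(np.diff(scores) >= 0)


def test_standardize_makes_decisions_scale_invariant():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(16, 5))
    y = np.array([1.0] * 8 + [-1.0] * 8)
    scale = np.array([1e-3, 1.0, 10.0, 100.0, 1e3])
    cfg = ElasticNetConfig(standardize=True)
    m1 = en.fit(X, y, cfg)
    m2 = en.fit(X * scale, y, cfg)
    T = rng.normal(size=(10, 5))
    l1, s1 = en.decide(m1, T)
    l2, s2 = en.decide(m2, T * scale)
    assert np.allclose(s1, s2, atol=1e-6)
    assert (l1 == l2).all()


def test_input_validation():
    X = np.ones((4, 2))
    with pytest.raises(ValueError, match="single-class"):
        en.fit(X, np.ones(4))
    with pytest.raises(ValueError, match="non-finite"):
        en.fit(np.array([[np.nan, 1], [1, 2], [0, 1], [2, 0]]),
               np.array([1.0, 1.0, -1.0, -1.0]))
    m = en.fit(np.random.default_rng(0).normal(size=(4, 2)),
               np.array([1.0, 1.0, -1.0, -1.0]))
    with pytest.raises(ValueError, match="dimensionality"):
        en.decide(m, np.ones((3, 5)))


def test_fit_is_deterministic():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(8, 6))
    y = np.array([1.0] * 4 + [-1.0] * 4)
    m1 = en.fit(X, y)
    m2 = en.fit(X, y)
    assert np.array_equal(m1.weights, m2.weights)
    assert m1.intercept == m2.intercept
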