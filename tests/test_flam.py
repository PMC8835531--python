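import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from evomet import flam
from evomet.flam import (
    _column_order,
    fit_flam,
    flam_objective,
    flsa_1d,
    lambda_max,
    per_metabolite_scan,
    predict,
    stability_select,
    tune_lambda,
)


def flsa_dual_oracle(r, w, lam):
    """Box-constrained dual QP solved by L-BFGS-B, polished by an exact
    active-set KKT solve."""
    n = len(r)
    if n == 1 or lam == 0:
        return np.asarray(r, dtype=float)
    D = np.diff(np.eye(n), axis=0)
    Winv = np.diag(1.0 / np.asarray(w, dtype=float))
    H = D @ Winv @ D.T
    c = D @ r
    res = minimize(lambda z: 0.5 * z @ H @ z - z @ c, np.zeros(n - 1),
                   jac=lambda z: H @ z - c, method="L-BFGS-B",
                   bounds=[(-lam, lam)] * (n - 1),
                   options=dict(ftol=1e-16, gtol=1e-12, maxiter=10000))
    z = res.x
    # polish: clamp near-active coordinates, solve the free block exactly
    for _ in range(4):
        at_lo = z < -lam + 1e-6 * max(lam, 1)
        at_hi = z > lam - 1e-6 * max(lam, 1)
        free = ~(at_lo | at_hi)
        z = np.where(at_lo, -lam, np.where(at_hi, lam, z))
        if free.any():
            rhs = c[free] - H[np.ix_(free, ~free)] @ z[~free]
            z[free] = np.linalg.solve(H[np.ix_(free, free)], rhs)
            z = np.clip(z, -lam, lam)
    return r - Winv @ D.T @ z


class TestFlsa:
    def test_lam_zero_identity(self, rng):
        r = rng.normal(size=7)
        np.testing.assert_array_equal(flsa_1d(r, np.ones(7), 0.0), r)

    def test_large_lam_gives_weighted_mean(self, rng):
        r = rng.normal(size=9)
        w = rng.uniform(0.5, 2.0, size=9)
        u = flsa_1d(r, w, 1e7)
        np.testing.assert_allclose(u, np.average(r, weights=w), atol=1e-9)

    def test_negative_lam_errors(self):
        with pytest.raises(ValueError, match="lam"):
            flsa_1d(np.ones(3), np.ones(3), -0.1)

    def test_matches_dual_qp_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 7))
            r = rng.normal(size=n) * 3
            w = rng.uniform(0.2, 3.0, size=n)
            lam = float(rng.uniform(0, 3))
            np.testing.assert_allclose(
                flsa_1d(r, w, lam), flsa_dual_oracle(r, w, lam), atol=1e-8)

    def test_solution_is_stationary(self, rng):
        """Perturbing the DP solution never lowers the objective."""
        r = rng.normal(size=6)
        w = rng.uniform(0.5, 2, size=6)
        lam = 0.7
        u = flsa_1d(r, w, lam)

        def obj(v):
            return 0.5 * np.sum(w * (r - v) ** 2) + lam * np.abs(np.diff(v)).sum()

        base = obj(u)
        for _ in range(200):
            assert obj(u + rng.normal(size=6) * 1e-4) >= base - 1e-12


class TestFitFlam:
    def test_full_shrinkage_above_lambda_max(self, rng):
        y = rng.normal(size=15)
        X = rng.uniform(size=(15, 4))
        lam = lambda_max(y, X, alpha=0.5)
        f = fit_flam(y, X, lam * 1.05, alpha=0.5)
        assert np.allclose(f.theta, 0)
        assert f.beta0 == pytest.approx(y.mean())
        assert len(f.selected) == 0

    def test_objective_non_increasing(self, rng):
        for _ in range(10):
            n, p = 12, 4
            y = rng.normal(size=n)
            X = rng.uniform(size=(n, p))
            f = fit_flam(y, X, lam=float(rng.uniform(0.05, 1.0)),
                         alpha=float(rng.uniform(0, 1)))
            assert np.all(np.diff(f.trace) <= 1e-9)

    def test_alpha1_p1_reduces_to_flsa(self, rng):
        x = np.sort(rng.uniform(size=10))[:, None]
        y = rng.normal(size=10)
        f = fit_flam(y, x, lam=0.3, alpha=1.0, tol=1e-13, max_iter=500)
        u = flsa_1d(y - y.mean(), np.ones(10), 0.3)
        np.testing.assert_allclose(f.theta[0], u - u.mean(), atol=1e-8)

    def test_small_fit_matches_convex_oracle(self, rng):
        """n=4, p=1: fitted component matches an SLSQP solve of the full
        nonsmooth objective via slack reformulation."""
        y = rng.normal(size=4)
        x = np.array([[0.1], [0.4], [0.7], [0.9]])
        lam, alpha = 0.15, 0.5
        f = fit_flam(y, x, lam, alpha, tol=1e-14, max_iter=2000)
        yc = y - y.mean()

        def obj(v):
            th, t = v[:4], v[4:]
            return 0.5 * np.sum((yc - th) ** 2) + lam * alpha * t.sum() \
                + lam * (1 - alpha) * np.sqrt(np.sum(th**2) + 1e-18)

        cons = [{"type": "eq", "fun": lambda v: v[:4].sum()}]
        for i in range(3):
            cons.append({"type": "ineq", "fun": lambda v, i=i: v[4 + i] - (v[i + 1] - v[i])})
            cons.append({"type": "ineq", "fun": lambda v, i=i: v[4 + i] + (v[i + 1] - v[i])})
        best = None
        for s in range(5):
            x0 = np.concatenate([np.random.default_rng(s).normal(size=4) * 0.5,
                                 np.ones(3)])
            r = minimize(obj, x0, method="SLSQP", constraints=cons,
                         options=dict(maxiter=2000, ftol=1e-14))
            if best is None or r.fun < best.fun:
                best = r
        ours = 0.5 * np.sum((yc - f.theta[0]) ** 2) + lam * alpha * \
            np.abs(np.diff(f.theta[0])).sum() + lam * (1 - alpha) * np.linalg.norm(f.theta[0])
        assert ours <= best.fun + 1e-8
        np.testing.assert_allclose(f.theta[0], best.x[:4], atol=1e-5)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="3 samples"):
            fit_flam(np.ones(2), np.ones((2, 1)), 0.1)
        with pytest.raises(ValueError, match="alpha"):
            fit_flam(rng.normal(size=5), np.ones((5, 1)), 0.1, alpha=1.5)

    def test_predict_reproduces_training_fit(self, rng):
        y = rng.normal(size=10)
        X = rng.uniform(size=(10, 3))
        f = fit_flam(y, X, 0.05, 0.5)
        np.testing.assert_allclose(predict(f, X), f.fitted_values(), atol=1e-10)


class TestTuneLambda:
    def test_grid_of_one(self, rng):
        y = rng.normal(size=9)
        X = rng.uniform(size=(9, 2))
        lam, _ = tune_lambda(y, X, grid=np.array([0.37]), rng=0)
        assert lam == 0.37

    def test_deterministic_under_fold_seed(self, rng):
        y = rng.normal(size=12)
        X = rng.uniform(size=(12, 3))
        l1, t1 = tune_lambda(y, X, rng=5)
        l2, t2 = tune_lambda(y, X, rng=5)
        assert l1 == l2
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_signal_picks_large_lambda(self):
        """Pure-noise responses: the one-SE rule stays near the null fit."""
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            y = rng.normal(size=20)
            X = rng.uniform(size=(20, 8))
            lam, tab = tune_lambda(y, X, rng=rng)
            if lam >= 0.1 * tab["lam"].max():
                hits += 1
        assert hits >= 17


class TestStability:
    def test_single_predictive_column_always_selected(self, rng):
        x = rng.uniform(size=20)
        y = 3 * x + rng.normal(size=20) * 0.05
        res = stability_select(y, pd.DataFrame({"mk": x}), n_perm=10, rng=0)
        assert res.selection_frequency["mk"] == 1.0
        assert res.stable_set == ["mk"]

    def test_identical_inputs_identical_results(self, rng):
        y = rng.normal(size=15)
        X = pd.DataFrame(rng.uniform(size=(15, 6)),
                         columns=[f"m{i}" for i in range(6)])
        r1 = stability_select(y, X, n_perm=8, rng=99)
        r2 = stability_select(y, X, n_perm=8, rng=99)
        assert r1.stable_set == r2.stable_set
        pd.testing.assert_series_equal(r1.selection_frequency, r2.selection_frequency)

    def test_pure_noise_rarely_yields_stable_markers(self):
        empty = 0
        reps = 10
        for s in range(reps):
            rng = np.random.default_rng(2000 + s)
            y = rng.normal(size=30)
            X = pd.DataFrame(rng.uniform(size=(30, 100)))
            res = stability_select(y, X, n_perm=20, rng=rng)
            empty += int(len(res.stable_set) == 0)
        assert empty >= reps - 1

    def test_recovers_causal_markers(self, rng):
        n, p = 30, 40
        X = pd.DataFrame(rng.uniform(size=(n, p)), columns=[f"m{i}" for i in range(p)])
        causal = ["m3", "m17", "m29"]
        y = sum(2.0 * X[c] for c in causal) + rng.normal(size=n) * 0.3
        res = stability_select(y.to_numpy(), X, n_perm=20, rng=7)
        found = set(res.stable_set) & set(causal)
        false = set(res.stable_set) - set(causal)
        assert len(found) == 3 and len(false) <= 4


class TestPerMetaboliteScan:
    def test_single_metabolite_union_is_its_set(self, rng):
        pops = [f"P{i}" for i in range(12)]
        X = pd.DataFrame(rng.uniform(size=(12, 5)), index=pops,
                         columns=[f"m{i}" for i in range(5)])
        y = pd.DataFrame({"met1": 3 * X["m2"] + rng.normal(size=12) * 0.05}, index=pops)
        sel, union = per_metabolite_scan(y, X, n_perm=5, seed=1)
        assert union == sel["met1"].stable_set

    def test_union_bounded_by_sum_of_sets(self, rng):
        pops = [f"P{i}" for i in range(15)]
        X = pd.DataFrame(rng.uniform(size=(15, 6)), index=pops,
                         columns=[f"m{i}" for i in range(6)])
        y = pd.DataFrame({
            "a": 2 * X["m0"] + rng.normal(size=15) * 0.1,
            "b": 2 * X["m0"] + 2 * X["m4"] + rng.normal(size=15) * 0.1,
        }, index=pops)
        sel, union = per_metabolite_scan(y, X, n_perm=5, seed=3)
        assert len(union) <= sum(len(r.stable_set) for r in sel.values())
        assert len(set(union)) == len(union)
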