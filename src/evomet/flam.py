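"""Fused lasso additive model (FLAM) with order-permutation stability
selection.

The model predicts a per-population response y (a metabolite's population
mean) from p marker allele-frequency columns X as a sum of piecewise-
constant component functions:

    minimize_{b0, theta}  1/2 || y - b0 - sum_j theta_j ||^2
                          + lam * sum_j [ alpha * TV_j(theta_j)
                                          + (1 - alpha) * ||theta_j||_2 ]

where TV_j is the total variation of theta_j taken in the order of
increasing x_j (tied x_j values fused into one level) and each theta_j is
constrained to mean zero (b0 absorbs the intercept). The total-variation
term makes each component a step function; the group term zeroes whole
components, giving marker selection.

Fitting is block coordinate descent: each block update solves the weighted
fused-lasso signal approximator (FLSA) on the partial residual in x_j-sorted
order, centers, then group-soft-thresholds. The FLSA subproblem is solved
*exactly* by a dynamic-programming message-passing scheme over piecewise-
linear derivative functions (O(n) per call in practice).

Because a single fit caps the number of recoverable predictors at the
number of populations and the finite descent path depends on the block
cycling order, selection is stabilized by rerunning the fit under random
predictor orderings and keeping markers selected in at least a threshold
fraction (default 50%) of runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

__all__ = [
    "flsa_1d",
    "FlamFit",
    "fit_flam",
    "predict",
    "flam_objective",
    "lambda_max",
    "tune_lambda",
    "StabilitySelection",
    "stability_select",
    "per_metabolite_scan",
]


# ---------------------------------------------------------------------------
# FLSA: exact weighted 1-D fused lasso signal approximator


@numba.njit(cache=False)
def _flsa_dp(r, w, lam):  # pragma: no cover - exercised via flsa_1d
    n = r.shape[0]
    u = np.empty(n)
    if n == 1:
        u[0] = r[0]
        return u
    maxseg = 2 * n + 4
    bp = np.empty(maxseg)
    A = np.empty(maxseg)
    B = np.empty(maxseg)
    nbp = np.empty(maxseg)
    nA = np.empty(maxseg)
    nB = np.empty(maxseg)
    tm_arr = np.empty(n)
    tp_arr = np.empty(n)
    # derivative of the first cost-to-go: one segment, no breakpoints
    m = 0
    A[0] = w[0]
    B[0] = -w[0] * r[0]
    for i in range(1, n):
        # clip the running derivative at -lam and +lam
        s = 0
        while s < m and A[s] * bp[s] + B[s] < -lam:
            s += 1
        tm = (-lam - B[s]) / A[s]
        sm = s
        s = m
        while s > 0 and A[s] * bp[s - 1] + B[s] > lam:
            s -= 1
        tp = (lam - B[s]) / A[s]
        sp = s
        k = sp - sm  # middle breakpoints kept
        nbp[0] = tm
        for t in range(k):
            nbp[1 + t] = bp[sm + t]
        nbp[k + 1] = tp
        nA[0] = 0.0
        nB[0] = -lam
        for t in range(k + 1):
            nA[1 + t] = A[sm + t]
            nB[1 + t] = B[sm + t]
        nA[k + 2] = 0.0
        nB[k + 2] = lam
        m = k + 2
        # add the i-th quadratic's derivative
        for t in range(m):
            bp[t] = nbp[t]
        for t in range(m + 1):
            A[t] = nA[t] + w[i]
            B[t] = nB[t] - w[i] * r[i]
        tm_arr[i] = tm
        tp_arr[i] = tp
    # root of the final derivative
    s = 0
    while s < m and A[s] * bp[s] + B[s] < 0.0:
        s += 1
    u[n - 1] = -B[s] / A[s]
    for i in range(n - 2, -1, -1):
        v = u[i + 1]
        if v < tm_arr[i + 1]:
            v = tm_arr[i + 1]
        elif v > tp_arr[i + 1]:
            v = tp_arr[i + 1]
        u[i] = v
    return u


def flsa_1d(r: np.ndarray, weights: np.ndarray | None = None, lam: float = 0.0) -> np.ndarray:
    """Exact minimizer of ``1/2 sum w_i (r_i - u_i)^2 + lam sum |u_{i+1} - u_i|``.

    Dynamic-programming message passing over piecewise-linear derivatives;
    the objective is strictly convex so the minimizer is unique.
    """
    r = np.asarray(r, dtype=np.float64)
    if weights is None:
        weights = np.ones_like(r)
    w = np.asarray(weights, dtype=np.float64)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if r.ndim != 1 or w.shape != r.shape:
        raise ValueError("r and weights must be 1-D of equal length")
    if np.any(w <= 0) or not np.all(np.isfinite(r)) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and inputs finite")
    if lam == 0 or r.size == 0:
        return r.copy()
    return _flsa_dp(r, w, float(lam))


# ---------------------------------------------------------------------------
# FLAM fitting


@dataclass
class _ColumnOrder:
    """Sort order and tie-group structure of one predictor column."""

    order: np.ndarray  # argsort of x, stable
    starts: np.ndarray  # group start offsets into the sorted vector
    sizes: np.ndarray  # group sizes (float, FLSA weights)
    x_groups: np.ndarray  # unique sorted x values


def _column_order(x: np.ndarray) -> _ColumnOrder:
    order = np.argsort(x, kind="stable")
    xs = x[order]
    new = np.empty(len(xs), dtype=bool)
    new[0] = True
    new[1:] = xs[1:] != xs[:-1]
    starts = np.flatnonzero(new)
    sizes = np.diff(np.append(starts, len(xs))).astype(np.float64)
    return _ColumnOrder(order, starts, sizes, xs[starts])


@numba.njit(cache=False)
def _flam_bcd(resid, theta, orders, starts, ngroups, sizes, lam_tv, lam_grp,
              cycle, max_iter, tol):  # pragma: no cover - exercised via fit_flam
    """Block coordinate descent cycles; returns (trace, n_cycles, converged).

    ``resid`` and ``theta`` are updated in place. ``orders``/``starts``/
    ``sizes`` are (p, n) padded arrays with ``ngroups[j]`` valid groups.
    """
    p, n = theta.shape
    rs = np.empty(n)
    rg = np.empty(n)
    wg = np.empty(n)
    trace = np.empty(max_iter + 1)

    def objective():
        sse = 0.0
        for t in range(n):
            sse += resid[t] * resid[t]
        pen = 0.0
        for j in range(p):
            G = ngroups[j]
            nrm = 0.0
            for t in range(n):
                nrm += theta[j, t] * theta[j, t]
            pen += lam_grp * np.sqrt(nrm)
            prev = theta[j, orders[j, starts[j, 0]]]
            for g in range(1, G):
                cur = theta[j, orders[j, starts[j, g]]]
                pen += lam_tv * abs(cur - prev)
                prev = cur
        return 0.5 * sse + pen

    obj = objective()
    trace[0] = obj
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for c in range(len(cycle)):
            j = cycle[c]
            G = ngroups[j]
            for t in range(n):
                rs[t] = resid[orders[j, t]] + theta[j, orders[j, t]]
            for g in range(G):
                s0 = starts[j, g]
                s1 = starts[j, g + 1] if g + 1 < G else n
                acc = 0.0
                for t in range(s0, s1):
                    acc += rs[t]
                wg[g] = s1 - s0
                rg[g] = acc / (s1 - s0)
            if lam_tv > 0.0 and G > 1:
                u = _flsa_dp(rg[:G], wg[:G], lam_tv)
            else:
                u = rg[:G].copy()
            # expand, center
            mean = 0.0
            for g in range(G):
                s0 = starts[j, g]
                s1 = starts[j, g + 1] if g + 1 < G else n
                for t in range(s0, s1):
                    rs[t] = u[g]  # reuse rs as the expanded sorted theta
                mean += u[g] * wg[g]
            mean /= n
            nrm = 0.0
            for t in range(n):
                rs[t] -= mean
                nrm += rs[t] * rs[t]
            nrm = np.sqrt(nrm)
            scale = 1.0
            if lam_grp > 0.0:
                scale = 1.0 - lam_grp / nrm if nrm > 0.0 else 0.0
                if scale < 0.0:
                    scale = 0.0
            for t in range(n):
                i = orders[j, t]
                tnew = scale * rs[t]
                resid[i] += theta[j, i] - tnew
                theta[j, i] = tnew
        obj_new = objective()
        trace[it] = obj_new
        if abs(obj - obj_new) <= tol * max(1.0, abs(obj)):
            converged = True
            obj = obj_new
            break
        obj = obj_new
    return trace[: it + 1], it, converged


@dataclass
class FlamFit:
    """A fitted fused lasso additive model."""

    beta0: float
    theta: np.ndarray  # (p, n) fitted component values per sample
    lam: float
    alpha: float
    objective: float
    trace: list = field(repr=False, default_factory=list)
    converged: bool = True
    columns: list[str] | None = None
    _orders: list[_ColumnOrder] | None = field(repr=False, default=None)

    @property
    def component_norms(self) -> np.ndarray:
        return np.linalg.norm(self.theta, axis=1)

    @property
    def selected(self) -> np.ndarray:
        """Indices of markers with a non-zero fitted component."""
        return np.flatnonzero(self.component_norms > 0)

    def fitted_values(self) -> np.ndarray:
        return self.beta0 + self.theta.sum(axis=0)


def _penalty(theta_j: np.ndarray, co: _ColumnOrder, alpha: float) -> float:
    u = theta_j[co.order][co.starts]
    tv = np.abs(np.diff(u)).sum() if len(u) > 1 else 0.0
    return alpha * tv + (1.0 - alpha) * np.linalg.norm(theta_j)


def flam_objective(y, theta, beta0, lam, alpha, orders) -> float:
    resid = y - beta0 - theta.sum(axis=0)
    pen = sum(_penalty(theta[j], orders[j], alpha) for j in range(theta.shape[0]))
    return 0.5 * float(resid @ resid) + lam * pen


def fit_flam(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    lam: float,
    alpha: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-7,
    theta_init: np.ndarray | None = None,
    column_cycle: np.ndarray | None = None,
) -> FlamFit:
    """Fit the FLAM objective by block coordinate descent.

    Each cycle updates every component: FLSA on the tie-fused partial
    residual in x_j order with penalty ``lam * alpha`` (weights = tie-group
    sizes), mean-centering, then group soft-thresholding at
    ``lam * (1 - alpha)``. The update is the exact block minimizer, so the
    objective is non-increasing. Stops when the relative objective change
    drops below ``tol``.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite inputs")

    orders = [_column_order(X[:, j]) for j in range(p)]
    beta0 = float(y.mean())
    theta = np.zeros((p, n)) if theta_init is None else theta_init.copy()
    resid = y - beta0 - theta.sum(axis=0)
    cycle = np.arange(p) if column_cycle is None else np.asarray(column_cycle, dtype=np.int64)

    order_mat = np.empty((p, n), dtype=np.int64)
    starts_mat = np.zeros((p, n), dtype=np.int64)
    sizes_mat = np.zeros((p, n), dtype=np.float64)
    ngroups = np.empty(p, dtype=np.int64)
    for j, co in enumerate(orders):
        order_mat[j] = co.order
        g = len(co.starts)
        ngroups[j] = g
        starts_mat[j, :g] = co.starts
        sizes_mat[j, :g] = co.sizes

    trace_arr, _, converged = _flam_bcd(
        resid, theta, order_mat, starts_mat, ngroups, sizes_mat,
        lam * alpha, lam * (1.0 - alpha), cycle, max_iter, tol,
    )
    if not converged:
        warnings.warn(f"FLAM did not converge in {max_iter} cycles", stacklevel=2)
    return FlamFit(beta0, theta, lam, alpha, float(trace_arr[-1]),
                   list(trace_arr), converged, columns, orders)


def predict(fit: FlamFit, Xnew: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Predict responses for new predictor rows.

    Each component is a step function of x_j; a new value takes the fitted
    level of the nearest training x_j (ties break toward the smaller x).
    """
    Xnew = np.asarray(Xnew, dtype=np.float64)
    out = np.full(Xnew.shape[0], fit.beta0)
    for j, co in enumerate(fit._orders):
        u = fit.theta[j][co.order][co.starts]  # level per unique x
        xg = co.x_groups
        pos = np.searchsorted(xg, Xnew[:, j])
        lo = np.clip(pos - 1, 0, len(xg) - 1)
        hi = np.clip(pos, 0, len(xg) - 1)
        pick = np.where(
            np.abs(Xnew[:, j] - xg[lo]) <= np.abs(xg[hi] - Xnew[:, j]), lo, hi
        )
        out += u[pick]
    return out


# ---------------------------------------------------------------------------
# lambda selection


def lambda_max(y: np.ndarray, X: np.ndarray, alpha: float = 0.5, rtol: float = 1e-3) -> float:
    """Smallest penalty (within ``rtol``) at which a first descent pass from
    the zero fit leaves every component at zero (the null fit)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    r0 = y - y.mean()
    norm0 = np.linalg.norm(r0)
    if norm0 == 0:
        return 0.0
    ub = np.inf
    if alpha < 1.0:
        ub = norm0 / (1.0 - alpha)
    if alpha > 0.0:
        fuse = 0.0
        for j in range(X.shape[1]):
            co = _column_order(X[:, j])
            rg = np.add.reduceat(r0[co.order], co.starts) / co.sizes
            cs = np.cumsum(co.sizes * (rg - np.average(rg, weights=co.sizes)))
            if len(cs) > 1:
                fuse = max(fuse, np.abs(cs[:-1]).max())
        ub = min(ub, fuse / alpha) if fuse > 0 else min(ub, 0.0)
    if not np.isfinite(ub) or ub <= 0:
        return 0.0

    def null_at(lam: float) -> bool:
        for j in range(X.shape[1]):
            co = _column_order(X[:, j])
            rg = np.add.reduceat(r0[co.order], co.starts) / co.sizes
            u = _flsa_dp(rg, co.sizes, lam * alpha) if lam * alpha > 0 and len(rg) > 1 else rg
            t = np.repeat(u, co.sizes.astype(np.int64))
            t = t - t.mean()
            if np.linalg.norm(t) > lam * (1.0 - alpha) + 1e-12:
                return False
        return True

    lo, hi = 0.0, ub
    while hi - lo > rtol * ub:
        mid = 0.5 * (lo + hi)
        if null_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _fit_path(y, X, lams, alpha, **kw):
    """Fits along a descending penalty path with warm starts."""
    fits = []
    theta = None
    for lam in lams:
        f = fit_flam(y, X, lam, alpha, theta_init=theta, **kw)
        theta = f.theta
        fits.append(f)
    return fits


def tune_lambda(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    alpha: float = 0.5,
    k_folds: int = 5,
    grid: np.ndarray | None = None,
    n_grid: int = 20,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the penalty by k-fold cross-validation with the one-SE rule.

    The default grid is log-spaced over three decades down from the null
    penalty ``lambda_max``. Returns (lambda*, CV table); lambda* is the
    largest grid value whose mean CV error is within one standard error of
    the minimum.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(rng)
    if grid is None:
        lmax = lambda_max(y, X, alpha)
        if lmax <= 0:
            lmax = 1.0
        grid = lmax * np.logspace(0, -3, n_grid)
    grid = np.sort(np.asarray(grid, dtype=np.float64))[::-1]
    if len(grid) == 1:
        return float(grid[0]), pd.DataFrame({"lam": grid, "cv_mean": [np.nan], "cv_se": [np.nan]})

    n = len(y)
    folds = rng.permutation(n) % k_folds
    errs = np.zeros((k_folds, len(grid)))
    for k in range(k_folds):
        test = folds == k
        fits = _fit_path(y[~test], X[~test], grid, alpha)
        for i, f in enumerate(fits):
            pred = predict(f, X[test])
            errs[k, i] = np.mean((y[test] - pred) ** 2)
    mean = errs.mean(axis=0)
    se = errs.std(axis=0, ddof=1) / np.sqrt(k_folds)
    best = int(np.argmin(mean))
    cutoff = mean[best] + se[best]
    # grid is descending: the first (largest) lambda within one SE
    star = float(grid[np.argmax(mean <= cutoff)])
    table = pd.DataFrame({"lam": grid, "cv_mean": mean, "cv_se": se})
    return star, table


# ---------------------------------------------------------------------------
# order-permutation stability selection


@dataclass
class StabilitySelection:
    """Marker selection frequencies over order-shuffled FLAM runs."""

    n_perm: int
    threshold: float
    selection_frequency: pd.Series  # marker -> fraction of runs selected
    stable_set: list[str]
    lam: float
    alpha: float
    seed: int | None = None


def stability_select(
    y: np.ndarray,
    X: pd.DataFrame,
    n_perm: int = 100,
    threshold: float = 0.5,
    cap: int | None = None,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.5,
    lam: float | None = None,
    retune_per_run: bool = False,
    k_folds: int = 5,
) -> StabilitySelection:
    """Stabilize FLAM marker selection by predictor-order permutation.

    Each run shuffles the block-update order of the predictors, fits at the
    cross-validated penalty, and records the selected set truncated to
    ``cap`` (default: the number of populations) by descending component
    norm. Markers selected in at least ``threshold`` of runs form the
    stable set. The penalty is tuned once on the unshuffled design and
    reused (``retune_per_run=True`` re-tunes inside every run).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X), columns=[f"m{j}" for j in range(np.asarray(X).shape[1])])
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if p < 1:
        raise ValueError("X needs at least one column")
    cap = n if cap is None else cap
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    Xv = X.to_numpy(dtype=np.float64)
    if lam is None and not retune_per_run:
        lam, _ = tune_lambda(y, Xv, alpha=alpha, k_folds=k_folds, rng=rng)

    counts = np.zeros(p)
    for _ in range(n_perm):
        perm = rng.permutation(p)
        lam_run = lam
        if retune_per_run:
            lam_run, _ = tune_lambda(y, Xv[:, perm], alpha=alpha, k_folds=k_folds, rng=rng)
        f = fit_flam(y, Xv[:, perm], lam_run, alpha)
        norms = f.component_norms
        sel = np.flatnonzero(norms > 0)
        if len(sel) > cap:
            sel = sel[np.argsort(norms[sel], kind="stable")[::-1][:cap]]
        counts[perm[sel]] += 1
    freq = pd.Series(counts / n_perm, index=X.columns)
    stable = [m for m in X.columns if freq[m] >= threshold]
    return StabilitySelection(n_perm, threshold, freq, stable, float(lam if lam is not None else np.nan), alpha, seed)


def per_metabolite_scan(
    responses: pd.DataFrame,
    freq_matrix: pd.DataFrame,
    n_perm: int = 100,
    threshold: float = 0.5,
    alpha: float = 0.5,
    seed: int | None = None,
    **kw,
) -> tuple[dict[str, StabilitySelection], list[str]]:
    """Stability-selected marker sets per metabolite, plus their union.

    ``responses``: populations x metabolites (one response value per
    population); ``freq_matrix``: populations x markers. Per-metabolite
    seeds are spawned deterministically from ``seed``.
    """
    common = [p for p in responses.index if p in freq_matrix.index]
    if len(common) < 3:
        raise ValueError("need >= 3 populations shared between responses and markers")
    R = responses.loc[common]
    Xm = freq_matrix.loc[common]
    root = np.random.SeedSequence(seed)
    children = root.spawn(R.shape[1])
    results: dict[str, StabilitySelection] = {}
    union: list[str] = []
    for ss, met in zip(children, R.columns):
        res = stability_select(
            R[met].to_numpy(), Xm, n_perm=n_perm, threshold=threshold,
            alpha=alpha, rng=np.random.default_rng(ss), **kw,
        )
        results[met] = res
        for m in res.stable_set:
            if m not in union:
                union.append(m)
    return results, union
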