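"""Cross-validated comparison against shrinkage regressors.

Stratified fold construction over trials, per-fold per-stimulus averaging
into observations, penalized regressors (ridge in closed form, lasso via
coordinate descent, sparse PLS via NIPALS with soft-thresholding),
derivative-free tuning of their scalar parameters by CV-error minimization,
and the overdetermined least-squares sweep over trials-per-observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.linear_model import Lasso

from . import core

__all__ = [
    "FoldPlan",
    "CVResult",
    "make_folds",
    "cv_error",
    "tune",
    "ridge_fit",
    "lasso_fit",
    "spls_fit",
    "overdetermined_sweep",
    "METHODS",
]

METHODS = ("roldsis", "ridge", "lasso", "spls")


@dataclass
class FoldPlan:
    """Per-stimulus partition of trial indices into k folds."""

    k: int
    assignment: list[np.ndarray]  # one (T_s,) int array of fold ids per stimulus
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        for fold_ids in self.assignment:
            counts = np.bincount(fold_ids, minlength=self.k)
            if counts.min() == 0:
                raise ValueError("every fold must receive at least one trial")
            if counts.max() - counts.min() > 1:
                raise ValueError("fold sizes within a stimulus must differ by <= 1")

    def fold_indices(self, stimulus: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment[stimulus] == fold)


@dataclass
class CVResult:
    """Cross-validation outcome for one method at one fold count."""

    method: str
    k: int
    fold_mse: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.fold_mse))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "params": self.params,
            "fold_mse": np.asarray(self.fold_mse).tolist(),
            "mean_mse": self.mean_mse,
        }


def make_folds(
    trial_counts: Sequence[int], k: int, seed: Optional[int] = None
) -> FoldPlan:
    """Uniform random stratified partition of trials into k folds."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assignment = []
    for count in trial_counts:
        if count < k:
            raise ValueError(
                f"stimulus with {count} trials cannot be split into {k} folds"
            )
        ids = np.resize(np.arange(k), count)  # balanced: sizes differ by <= 1
        rng.shuffle(ids)
        assignment.append(ids)
    return FoldPlan(k=k, assignment=assignment, seed=seed)


# --- penalized regressors -------------------------------------------------

def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Closed-form ridge on centered data.

    Minimizes ||y - a - Xb||^2 + lam ||b||^2. Uses the M x M dual form when
    N > M (HDLSS) and the primal N x N form otherwise; the two agree.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    m, n = X.shape
    if n > m:
        G = Xc @ Xc.T + lam * np.eye(m)
        b = Xc.T @ np.linalg.solve(G, yc)
    else:
        A = Xc.T @ Xc + lam * np.eye(n)
        b = np.linalg.solve(A, Xc.T @ yc)
    a = ym - float(b @ xm)
    return a, b


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """L1-penalized least squares: ||y - a - Xb||^2 + lam ||b||_1.

    Delegates to coordinate descent (scikit-learn); the intercept is handled
    by centering. The sklearn objective 1/(2M)||.||^2 + alpha||b||_1 maps to
    ours with alpha = lam / (2M).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if lam == 0:
        # Unpenalized limit: minimum-norm least squares.
        xm, ym = X.mean(axis=0), y.mean()
        b, *_ = np.linalg.lstsq(X - xm, y - ym, rcond=None)
        return ym - float(b @ xm), b
    model = Lasso(
        alpha=lam / (2 * X.shape[0]), fit_intercept=True,
        max_iter=50000, tol=1e-10,
    )
    model.fit(X, y)
    return float(model.intercept_), model.coef_.copy()


def spls_fit(
    X: np.ndarray, y: np.ndarray, zeta: float, n_components: int
) -> tuple[float, np.ndarray]:
    """Sparse partial least squares via NIPALS with soft-thresholding.

    For each of ``n_components`` latent directions, the covariance direction
    w = Xc'r is soft-thresholded at zeta * max|w| (zeta in (0, 1): larger
    means sparser), normalized, and the response residual is deflated by the
    latent score. Coefficients are assembled by regressing y on the latent
    scores.
    """
    if not 0 < zeta < 1:
        raise ValueError("zeta must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = X.shape
    if not 1 <= n_components <= min(m - 1, n):
        raise ValueError(
            f"n_components must be in [1, {min(m - 1, n)}], got {n_components}"
        )
    xm, ym = X.mean(axis=0), y.mean()
    Xc = X - xm
    r = y - ym
    Xd = Xc.copy()
    weights, scores = [], []
    for _ in range(n_components):
        w = Xd.T @ r
        peak = np.abs(w).max()
        if peak == 0:
            break
        w = np.sign(w) * np.maximum(np.abs(w) - zeta * peak, 0.0)
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            break
        weights.append(w)
        scores.append(t)
        # Deflate both the predictors and the response residual.
        p = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        r = r - t * (float(t @ r) / tt)
    if not weights:
        return ym, np.zeros(n)
    T = np.column_stack(scores)
    # y ~ T gives the coefficients in latent space; map back through the
    # (deflation-corrected) weight matrix.
    W = np.column_stack(weights)
    P = Xc.T @ T / (T ** 2).sum(axis=0)
    q, *_ = np.linalg.lstsq(T, y - ym, rcond=None)
    R = W @ np.linalg.pinv(P.T @ W)
    b = R @ q
    return ym - float(b @ xm), b


# --- cross-validation -----------------------------------------------------

def _fold_observations(
    trials: Sequence[np.ndarray], y: np.ndarray, plan: FoldPlan, fold: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Train/test design for one CV step.

    Training observations are the per-stimulus averages of each training
    fold (M * (k-1) rows, attribute repeated per stimulus); test
    observations are the per-stimulus averages of the held-out fold.
    """
    X_train, y_train, X_test, y_test = [], [], [], []
    for s, t in enumerate(trials):
        for f in range(plan.k):
            avg = t[plan.fold_indices(s, f)].mean(axis=0)
            if f == fold:
                X_test.append(avg)
                y_test.append(y[s])
            else:
                X_train.append(avg)
                y_train.append(y[s])
    return (
        np.vstack(X_train), np.asarray(y_train),
        np.vstack(X_test), np.asarray(y_test),
    )


def _fit_method(method: str, X: np.ndarray, y: np.ndarray, params: dict):
    if method == "roldsis":
        f = core.fit(core.ObservationSet(X, y))
        return f.a, f.b
    if method == "ridge":
        return ridge_fit(X, y, params["lam"])
    if method == "lasso":
        return lasso_fit(X, y, params["lam"])
    if method == "spls":
        return spls_fit(X, y, params["zeta"], params["n_components"])
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def cv_error(
    method: str,
    folds: FoldPlan,
    trials: Sequence[np.ndarray],
    y: np.ndarray,
    params: Optional[dict] = None,
) -> CVResult:
    """k-fold CV error of one method with fixed parameters.

    Each fold in turn is held out; the model is fitted on the averaged
    observations of the remaining folds and scored by mean squared
    prediction error on the held-out averages.
    """
    params = dict(params or {})
    trials = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trials]
    y = np.asarray(y, dtype=float).ravel()
    fold_mse = np.empty(folds.k)
    for fold in range(folds.k):
        X_tr, y_tr, X_te, y_te = _fold_observations(trials, y, folds, fold)
        a, b = _fit_method(method, X_tr, y_tr, params)
        pred = a + X_te @ b
        fold_mse[fold] = float(np.mean((pred - y_te) ** 2))
    return CVResult(method=method, k=folds.k, fold_mse=fold_mse, params=params)


def tune(
    method: str,
    folds: FoldPlan,
    trials: Sequence[np.ndarray],
    y: np.ndarray,
    search_space: Optional[dict] = None,
) -> CVResult:
    """Minimize the CV error over the method's scalar parameters.

    Ridge/lasso: bounded Brent search on log10(lambda). SPLS: exhaustive
    sweep over the component count combined with a bounded 1-D search on
    zeta. RoLDSIS has no tunable parameter and is rejected.
    """
    if method == "roldsis":
        raise ValueError("roldsis has no tunable parameter")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    search_space = dict(search_space or {})

    if method in ("ridge", "lasso"):
        log_lo, log_hi = search_space.get("log10_lambda", (-6.0, 6.0))

        def objective(log_lam: float) -> float:
            return cv_error(
                method, folds, trials, y, {"lam": 10.0 ** log_lam}
            ).mean_mse

        res = minimize_scalar(
            objective, bounds=(log_lo, log_hi), method="bounded",
            options={"xatol": 1e-3},
        )
        # Guard against local minima of a noisy CV curve with a coarse scan.
        grid = np.linspace(log_lo, log_hi, 25)
        grid_vals = [objective(g) for g in grid]
        best_grid = grid[int(np.argmin(grid_vals))]
        candidates = [res.x, best_grid]
        best = min(candidates, key=objective)
        return cv_error(method, folds, trials, y, {"lam": float(10.0 ** best)})

    # SPLS
    m = len(trials)
    max_k = search_space.get("max_components", m - 1)
    best_result = None
    for ncomp in range(1, max_k + 1):
        def objective(zeta: float, ncomp=ncomp) -> float:
            return cv_error(
                "spls", folds, trials, y,
                {"zeta": zeta, "n_components": ncomp},
            ).mean_mse

        res = minimize_scalar(
            objective, bounds=(0.01, 0.99), method="bounded",
            options={"xatol": 1e-3},
        )
        result = cv_error(
            "spls", folds, trials, y,
            {"zeta": float(res.x), "n_components": ncomp},
        )
        if best_result is None or result.mean_mse < best_result.mean_mse:
            best_result = result
    return best_result


def overdetermined_sweep(
    trials: Sequence[np.ndarray],
    y: np.ndarray,
    group_sizes: Sequence[int] = (1, 2, 3, 4, 5, 6),
    seed: Optional[int] = None,
) -> dict[int, float]:
    """In-sample RMS error of OLS at several trials-per-observation settings.

    For each group size g, each stimulus's trials are randomly partitioned
    into disjoint groups of g (leftover trials dropped) and averaged into
    observations carrying the stimulus attribute; OLS requires more
    observations than features. Larger g averages away more noise, so on
    noisy data the RMS error shrinks as g grows.
    """
    trials = [np.atleast_2d(np.asarray(t, dtype=float)) for t in trials]
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n_features = trials[0].shape[1]
    out: dict[int, float] = {}
    for g in group_sizes:
        X_rows, y_rows = [], []
        for s, t in enumerate(trials):
            order = rng.permutation(t.shape[0])
            n_groups = t.shape[0] // g
            for j in range(n_groups):
                idx = order[j * g:(j + 1) * g]
                X_rows.append(t[idx].mean(axis=0))
                y_rows.append(y[s])
        X = np.vstack(X_rows)
        yy = np.asarray(y_rows)
        if X.shape[0] <= n_features:
            raise ValueError(
                f"group size {g} yields {X.shape[0]} observations for "
                f"{n_features} features: system is not overdetermined"
            )
        design = np.hstack([np.ones((X.shape[0], 1)), X])
        coef, *_ = np.linalg.lstsq(design, yy, rcond=None)
        resid = yy - design @ coef
        out[g] = float(np.sqrt(np.mean(resid ** 2)))
    return out
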