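"""PLS and LS-SVM regression with cross-validated hyperparameter selection.

PLS here is univariate-y partial least squares fitted by the NIPALS deflation
recursion on mean-centred data (no autoscaling — scaling is the pretreatment
module's business).  Because NIPALS components are nested, one fit at
``max_pcs`` yields the regression vector for every smaller component count,
which the cross-validation helpers exploit heavily: a k-fold scan over
1..max_pcs components costs k fits, not k*max_pcs.

LS-SVM is least-squares support vector regression with an RBF kernel
K(x, z) = exp(-||x - z||^2 / sigma2).  The denominator convention is sigma^2
(not 2*sigma^2) so that the grid-searched parameter is directly the sigma^2
the chemometrics literature reports.  Fitting solves the single saddle-point
(KKT) linear system

    [ 0   1^T           ] [ b     ]   [ 0 ]
    [ 1   K + I/gamma   ] [ alpha ] = [ y ]

so the model is dense (every training sample is a support vector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ModelError

__all__ = [
    "PLSModel",
    "LSSVMModel",
    "pls_fit",
    "pls_predict",
    "select_pcs_cv",
    "lssvm_fit",
    "lssvm_predict",
    "grid_search_lssvm",
    "kfold_indices",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_SIGMA2_GRID",
]

#: log2-spaced default hyperparameter grids, 2^-5 .. 2^15 step 2^2.
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_SIGMA2_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic k-fold partition of range(n) from a seed.

    Samples are permuted once and dealt into ``folds`` contiguous blocks of
    near-equal size (the first n % folds blocks get the extra sample).
    """
    if folds < 2:
        raise ConfigError(f"folds must be >= 2, got {folds}")
    folds = min(folds, n)
    perm = np.random.default_rng(seed).permutation(n)
    sizes = np.full(folds, n // folds)
    sizes[: n % folds] += 1
    out, pos = [], 0
    for s in sizes:
        out.append(np.sort(perm[pos : pos + s]))
        pos += s
    return out


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """Fitted univariate PLS regression.

    ``coef``/``intercept`` give predictions identical (<=1e-10) to the latent
    path through weights/loadings; ``n_components`` may be smaller than
    requested if a deflation step produced a zero weight vector, in which case
    ``truncated`` is set.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x k
    x_loadings: np.ndarray   # p x k
    y_loadings: np.ndarray   # k
    coef: np.ndarray         # p
    intercept: float
    coef_path: np.ndarray = field(repr=False, default=None)  # p x k, per 1..k comps
    truncated: bool = False


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, k: int):
    """NIPALS on centred data; returns (W, P, q, n_eff).

    W, P are p x n_eff, q length n_eff.  Stops early (n_eff < k) when the
    weight vector or score norm collapses.
    """
    p = Xc.shape[1]
    W = np.empty((p, k))
    P = np.empty((p, k))
    q = np.empty(k)
    X = Xc.copy()
    y = yc.copy()
    n_eff = 0
    for j in range(k):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= 1e-12:
            break
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-12:
            break
        pj = X.T @ t / tt
        qj = float(y @ t) / tt
        X -= np.outer(t, pj)
        y = y - qj * t
        W[:, j], P[:, j], q[j] = w, pj, qj
        n_eff += 1
    return W[:, :n_eff], P[:, :n_eff], q[:n_eff], n_eff


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vectors for every nested component count.

    B_k = W_k (P_k^T W_k)^{-1} q_k; computed incrementally via the
    triangular structure of P^T W.
    """
    k = W.shape[1]
    if k == 0:
        return np.zeros((W.shape[0], 0))
    PtW = P.T @ W  # upper triangular with unit-ish diagonal in exact arithmetic
    B = np.empty((W.shape[0], k))
    for j in range(1, k + 1):
        r = np.linalg.solve(PtW[:j, :j], q[:j])
        B[:, j - 1] = W[:, :j] @ r
    return B


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit mean-centred univariate PLS with the requested component count."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ConfigError(f"{n} rows but {y.size} targets")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ModelError("X and y must be finite")
    max_allowed = min(n - 1, p)
    if not 1 <= n_components <= max_allowed:
        raise ConfigError(
            f"n_components must be in [1, {max_allowed}] for n={n}, p={p}; "
            f"got {n_components}"
        )
    if np.std(y) == 0:
        raise ModelError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, n_eff = _nipals_path(X - x_mean, y - y_mean, n_components)
    if n_eff == 0:
        raise ModelError("first PLS weight vector has zero norm (X constant?)")
    Bpath = _coef_path(W, P, q)
    coef = Bpath[:, -1]
    return PLSModel(
        n_components=n_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=y_mean - float(x_mean @ coef),
        coef_path=Bpath,
        truncated=n_eff < n_components,
    )


def pls_predict(model: PLSModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Predict with the fitted model (optionally truncated to fewer components)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if n_components is None or n_components == model.n_components:
        coef = model.coef
    else:
        if not 1 <= n_components <= model.n_components:
            raise ConfigError(
                f"n_components must be in [1, {model.n_components}]"
            )
        coef = model.coef_path[:, n_components - 1]
    return (X - model.x_mean) @ coef + model.y_mean


def cv_rmse_per_component(
    X: np.ndarray,
    y: np.ndarray,
    max_pcs: int,
    fold_plan: list[np.ndarray],
) -> np.ndarray:
    """k-fold CV RMSE for every component count 1..kmax in one sweep.

    kmax is max_pcs capped at min over folds of (n_train_fold - 1, p).  One
    NIPALS fit per fold provides the whole nested coefficient path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    kmax = min(max_pcs, p, min(n - f.size for f in fold_plan) - 1)
    if kmax < 1:
        raise ConfigError("fold plan leaves no room for a single component")
    sq = np.zeros(kmax)
    counts = np.zeros(kmax)
    all_idx = np.arange(n)
    for val in fold_plan:
        train = np.setdiff1d(all_idx, val, assume_unique=True)
        Xt, yt = X[train], y[train]
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        W, P, q, n_eff = _nipals_path(Xt - xm, yt - ym, kmax)
        if n_eff == 0:
            raise ModelError("PLS collapsed on a CV fold (constant X block)")
        B = _coef_path(W, P, q)  # p x n_eff
        pred = (X[val] - xm) @ B + ym  # n_val x n_eff
        err = pred - y[val][:, None]
        sq[:n_eff] += (err**2).sum(axis=0)
        if n_eff < kmax:
            # model truncated: reuse the deepest available component count
            sq[n_eff:] += (err[:, -1] ** 2).sum()
        counts[:] += val.size
    return np.sqrt(sq / counts)


def select_pcs_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_pcs: int = 30,
    folds: int = 10,
    seed: int = 0,
    fold_plan: list[np.ndarray] | None = None,
) -> tuple[int, float]:
    """Pick the component count minimizing k-fold CV RMSE (ties -> fewer)."""
    X = np.asarray(X, dtype=float)
    if fold_plan is None:
        fold_plan = kfold_indices(X.shape[0], folds, seed)
    rmse = cv_rmse_per_component(X, y, max_pcs, fold_plan)
    best = int(np.argmin(rmse))  # argmin takes the first minimum: fewest comps
    return best + 1, float(rmse[best])


# ---------------------------------------------------------------------------
# LS-SVM
# ---------------------------------------------------------------------------


@dataclass
class LSSVMModel:
    support_X: np.ndarray
    alpha: np.ndarray
    b: float
    gamma: float
    sigma2: float


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """K_ij = exp(-||a_i - b_j||^2 / sigma2)."""
    a2 = (A**2).sum(axis=1)[:, None]
    b2 = (B**2).sum(axis=1)[None, :]
    d2 = np.maximum(a2 + b2 - 2.0 * (A @ B.T), 0.0)
    return np.exp(-d2 / sigma2)


def lssvm_fit(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> LSSVMModel:
    """Solve the LS-SVM KKT system for dual coefficients and bias."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if gamma <= 0 or sigma2 <= 0:
        raise ConfigError(f"gamma and sigma2 must be > 0, got {gamma}, {sigma2}")
    n = X.shape[0]
    if y.size != n:
        raise ConfigError(f"{n} rows but {y.size} targets")
    K = rbf_kernel(X, X, sigma2)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ModelError(
            "LS-SVM KKT system is numerically singular; try a smaller gamma"
        ) from exc
    return LSSVMModel(support_X=X.copy(), alpha=sol[1:], b=float(sol[0]),
                      gamma=float(gamma), sigma2=float(sigma2))


def lssvm_predict(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """yhat(x) = sum_j alpha_j K(x, x_j) + b."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return rbf_kernel(X, model.support_X, model.sigma2) @ model.alpha + model.b


def grid_search_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    gamma_grid=DEFAULT_GAMMA_GRID,
    sigma2_grid=DEFAULT_SIGMA2_GRID,
    folds: int = 10,
    seed: int = 0,
    fold_plan: list[np.ndarray] | None = None,
) -> tuple[float, float, float]:
    """Exhaustive CV-RMSE minimization over the (gamma, sigma2) grid.

    Returns (gamma, sigma2, cv_rmse).  Ties break toward smaller gamma (less
    overfitting), then larger sigma2 (smoother kernel).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if fold_plan is None:
        fold_plan = kfold_indices(n, folds, seed)
    # Pairwise squared distances once; per grid point only the exp changes.
    sq = (X**2).sum(axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    all_idx = np.arange(n)
    best = None
    for sigma2 in sorted(set(float(s) for s in sigma2_grid), reverse=True):
        Kfull = np.exp(-D2 / sigma2)
        for gamma in sorted(set(float(g) for g in gamma_grid)):
            sse, cnt = 0.0, 0
            for val in fold_plan:
                train = np.setdiff1d(all_idx, val, assume_unique=True)
                nt = train.size
                A = np.zeros((nt + 1, nt + 1))
                A[0, 1:] = 1.0
                A[1:, 0] = 1.0
                A[1:, 1:] = Kfull[np.ix_(train, train)] + np.eye(nt) / gamma
                try:
                    sol = np.linalg.solve(A, np.concatenate(([0.0], y[train])))
                except np.linalg.LinAlgError:
                    sse = np.inf
                    break
                pred = Kfull[np.ix_(val, train)] @ sol[1:] + sol[0]
                sse += float(((pred - y[val]) ** 2).sum())
                cnt += val.size
            rmse = np.sqrt(sse / cnt) if np.isfinite(sse) else np.inf
            key = (rmse, gamma, -sigma2)
            if best is None or key < best[0]:
                best = (key, gamma, sigma2, rmse)
    if best is None or not np.isfinite(best[3]):
        raise ModelError("no (gamma, sigma2) grid point produced a solvable system")
    return best[1], best[2], best[3]
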