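"""Characteristic-wavelength selection: SPA, CARS and random frog.

All three selectors score candidate band subsets with the same criterion,
RMSECV: the minimum k-fold cross-validated RMSE of a univariate PLS model
over 1..max_pcs latent components, fitted on the candidate columns.  A single
fold partition is drawn from the seed at the start of each selector call and
reused for every candidate subset so that scores are comparable.

* SPA (successive projections algorithm) grows chains of mutually
  near-orthogonal columns: from each candidate start column it repeatedly
  projects the unselected columns onto the orthogonal complement of the span
  of the selected ones and appends the column with the largest residual norm.
  Every chain prefix of length k_min..k_max is scored by RMSECV and the best
  prefix wins (ties: fewer variables, then lower start index).

* CARS (competitive adaptive reweighted sampling) runs N Monte Carlo rounds.
  Each round fits PLS on a random 80 % subsample restricted to the live
  variable set, weights variables by normalized |regression coefficient|,
  enforces an exponentially decaying retention count (all p variables at
  round 1 down to 2 at round N), resamples the retained variables with
  probability proportional to weight, and records the live set's RMSECV.  The
  recorded set with the smallest RMSECV is returned.

* Random frog performs a stochastic subset walk: candidate subsets of
  normally perturbed size are proposed by weight-guided growth or shrinkage,
  accepted if their RMSECV improves (or with a small probability otherwise),
  and every variable's visit frequency over the iterations becomes its
  selection probability.  The top-k most probable bands are returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ModelError
from .regression import cv_rmse_per_component, kfold_indices, pls_fit

__all__ = [
    "SelectionResult",
    "rmsecv",
    "spa_select",
    "cars_select",
    "frog_select",
    "cars_retention_schedule",
    "select",
]


@dataclass
class SelectionResult:
    """Chosen band indices plus the evidence trail that justified them.

    ``score_trace`` holds per-candidate-subset RMSECV values for spa/cars and
    per-band selection probabilities for frog; ``best_pcs`` is the latent
    component count of the winning inner PLS model.
    """

    method: str
    indices: np.ndarray
    n_selected: int
    score_trace: np.ndarray
    best_pcs: int
    seed: int
    rmsecv: float = math.nan
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size != np.unique(self.indices).size:
            raise ConfigError("selected indices must be unique")
        if not np.all(np.diff(self.indices) > 0):
            self.indices = np.sort(self.indices)
        self.n_selected = int(self.indices.size)

    def to_dict(self, wavelengths: np.ndarray | None = None) -> dict:
        out = {
            "method": self.method,
            "indices": self.indices.tolist(),
            "n_selected": self.n_selected,
            "best_pcs": int(self.best_pcs),
            "seed": int(self.seed),
            "rmsecv": None if math.isnan(self.rmsecv) else float(self.rmsecv),
            "score_trace": np.asarray(self.score_trace, dtype=float).tolist(),
        }
        if wavelengths is not None:
            out["wavelengths_nm"] = np.asarray(wavelengths)[self.indices].tolist()
        return out


def full_selection(n_bands: int, seed: int = 0) -> SelectionResult:
    """The no-selection baseline: every band."""
    return SelectionResult(
        method="full", indices=np.arange(n_bands), n_selected=n_bands,
        score_trace=np.array([]), best_pcs=0, seed=seed,
    )


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    subset,
    max_pcs: int = 10,
    folds: int = 10,
    seed: int = 0,
    fold_plan: list[np.ndarray] | None = None,
) -> tuple[float, int]:
    """Minimum k-fold CV RMSE of PLS on X[:, subset] over 1..max_pcs components.

    Returns (rmsecv, best_pcs); component counts are capped by the per-fold
    sample budget and the subset size.  Fold assignment is deterministic in
    the seed (or taken from an explicit ``fold_plan``).
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ConfigError("empty subset")
    X = np.asarray(X, dtype=float)
    if fold_plan is None:
        fold_plan = kfold_indices(X.shape[0], folds, seed)
    rmse = cv_rmse_per_component(X[:, subset], y, max_pcs, fold_plan)
    best = int(np.argmin(rmse))
    return float(rmse[best]), best + 1


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------


def spa_chain(X: np.ndarray, start: int, k_max: int) -> list[int]:
    """Projection chain from one start column.

    Maintains the residuals of all columns against the span of the selected
    ones; each step appends the column of maximum residual norm.  Stops early
    on rank collapse (all residual norms <= 1e-12).
    """
    R = np.array(X, dtype=float, copy=True)
    chain = [int(start)]
    selected = np.zeros(X.shape[1], dtype=bool)
    selected[start] = True
    for _ in range(1, k_max):
        u = R[:, chain[-1]]
        un = float(u @ u)
        if un <= 1e-24:
            break
        R = R - np.outer(u, (u @ R) / un)
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= 1e-12:
            break
        chain.append(j)
        selected[j] = True
    return chain


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    k_min: int = 2,
    k_max: int = 25,
    folds: int = 10,
    seed: int = 0,
    max_pcs: int = 10,
    starts=None,
) -> SelectionResult:
    """Successive projections algorithm with RMSECV prefix scoring.

    Every candidate start column (default: all columns) seeds a chain of
    length k_max; every prefix of length k_min..k_max is scored and the
    global minimizer returned.  Ties prefer fewer variables, then the lower
    start index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= k_min <= k_max <= p:
        raise ConfigError(f"need 1 <= k_min <= k_max <= {p}")
    fold_plan = kfold_indices(n, folds, seed)
    starts = range(p) if starts is None else starts
    best = None  # (rmsecv, n_vars, start, subset, pcs)
    trace = []
    for start in starts:
        chain = spa_chain(X, start, k_max)
        for k in range(k_min, len(chain) + 1):
            subset = np.sort(np.array(chain[:k]))
            score, pcs = rmsecv(X, y, subset, max_pcs=max_pcs, fold_plan=fold_plan)
            trace.append(score)
            key = (score, k, start)
            if best is None or key < best[0]:
                best = (key, subset, pcs)
    if best is None:
        raise ModelError("SPA found no scorable subset")
    (score, _, _), subset, pcs = best
    return SelectionResult(
        method="spa", indices=subset, n_selected=subset.size,
        score_trace=np.asarray(trace), best_pcs=pcs, seed=seed, rmsecv=score,
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------


def cars_retention_schedule(p: int, n_runs: int) -> np.ndarray:
    """Enforced exponential decay ratios r_i = a*exp(-k*i), i = 1..n_runs.

    The two boundary constraints fix the constants: all p variables survive
    round 1 (r_1 = 1) and exactly 2 survive round n_runs (r_N = 2/p), giving
    a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1).
    """
    if n_runs < 2 or p < 2:
        raise ConfigError("CARS needs n_runs >= 2 and p >= 2")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(p / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 1000,
    mc_fraction: float = 0.8,
    folds: int = 10,
    seed: int = 0,
    max_pcs: int = 10,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ConfigError("CARS needs at least 2 bands")
    if not 0 < mc_fraction <= 1:
        raise ConfigError("mc_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    fold_plan = kfold_indices(n, folds, seed)
    ratios = cars_retention_schedule(p, n_runs)
    n_mc = max(2, int(round(mc_fraction * n)))
    live = np.arange(p)
    trace = np.full(n_runs, np.nan)
    recorded = []  # (rmsecv, pcs, live set) per completed run
    for i in range(n_runs):
        sub = np.sort(rng.choice(n, size=n_mc, replace=False))
        # PLS coefficient weights on the Monte Carlo subsample.
        ncomp = min(max_pcs, n_mc - 1, live.size)
        model = pls_fit(X[np.ix_(sub, live)], y[sub], ncomp)
        w = np.abs(model.coef)
        total = w.sum()
        w = np.full(live.size, 1.0 / live.size) if total <= 0 else w / total
        # Enforced decay fixes how many variables survive this round; the
        # adaptive reweighted sampling decides which: a weighted draw of
        # `keep` distinct variables, so low-weight bands can survive by luck
        # but the live-set size tracks the schedule exactly.
        keep = max(2, min(live.size, math.ceil(ratios[i] * p)))
        probs = w / w.sum()
        live = np.sort(rng.choice(live, size=keep, replace=False, p=probs))
        if live.size < 2:
            break
        score, pcs = rmsecv(X, y, live, max_pcs=max_pcs, fold_plan=fold_plan)
        trace[i] = score
        recorded.append((score, pcs, live.copy()))
    if not recorded:
        raise ModelError("CARS collapsed before recording any subset")
    scores = np.array([r[0] for r in recorded])
    order = np.argmin(scores)  # first minimum: earliest (largest) subset on ties
    best_score, best_pcs, best_set = recorded[int(order)]
    # Tie-break per contract: smaller subset, then lexicographically smallest.
    ties = [r for r in recorded if r[0] == best_score]
    if len(ties) > 1:
        ties.sort(key=lambda r: (r[2].size, tuple(r[2])))
        best_score, best_pcs, best_set = ties[0]
    return SelectionResult(
        method="cars", indices=best_set, n_selected=best_set.size,
        score_trace=trace, best_pcs=best_pcs, seed=seed, rmsecv=best_score,
        extras={"n_runs_completed": len(recorded)},
    )


# ---------------------------------------------------------------------------
# Random frog
# ---------------------------------------------------------------------------


def _pls_weights(X: np.ndarray, y: np.ndarray, subset: np.ndarray, max_pcs: int) -> np.ndarray:
    ncomp = min(max_pcs, X.shape[0] - 1, subset.size)
    model = pls_fit(X[:, subset], y, ncomp)
    return np.abs(model.coef)


def frog_select(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 1000,
    top_k: int = 10,
    seed: int = 0,
    q_init: int | None = None,
    theta: float = 0.3,
    eta: float = 0.1,
    folds: int = 10,
    max_pcs: int = 10,
) -> SelectionResult:
    """Random frog subset walk; returns the top_k bands by visit probability."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    if not 1 <= top_k <= p:
        raise ConfigError(f"top_k must be in [1, {p}]")
    if q_init is None:
        q_init = max(2, p // 10)
    q_init = min(max(1, q_init), p)
    rng = np.random.default_rng(seed)
    fold_plan = kfold_indices(n, folds, seed)
    current = np.sort(rng.choice(p, size=q_init, replace=False))
    current_score, _ = rmsecv(X, y, current, max_pcs=max_pcs, fold_plan=fold_plan)
    visits = np.zeros(p)
    for _ in range(n_iter):
        q_star = int(round(rng.normal(current.size, theta * current.size)))
        q_star = min(max(q_star, 1), p)
        if q_star > current.size:
            pool_size = min(p - current.size, 3 * (q_star - current.size))
            candidates = np.setdiff1d(np.arange(p), current, assume_unique=False)
            pool = rng.choice(candidates, size=pool_size, replace=False)
            union = np.sort(np.concatenate([current, pool]))
            w = _pls_weights(X, y, union, max_pcs)
            keep = np.argsort(-w, kind="stable")[:q_star]
            candidate = np.sort(union[keep])
        elif q_star < current.size:
            w = _pls_weights(X, y, current, max_pcs)
            keep = np.argsort(-w, kind="stable")[:q_star]
            candidate = np.sort(current[keep])
        else:
            candidate = current
        if candidate.size == current.size and np.array_equal(candidate, current):
            cand_score = current_score
        else:
            cand_score, _ = rmsecv(X, y, candidate, max_pcs=max_pcs, fold_plan=fold_plan)
        if cand_score <= current_score or rng.random() < eta * (
            current_score / cand_score
        ):
            current, current_score = candidate, cand_score
        visits[current] += 1
    probs = visits / n_iter
    # top_k by probability; ties -> lower index (stable sort on -probs).
    top = np.sort(np.argsort(-probs, kind="stable")[:top_k])
    score, pcs = rmsecv(X, y, top, max_pcs=max_pcs, fold_plan=fold_plan)
    return SelectionResult(
        method="frog", indices=top, n_selected=top.size, score_trace=probs,
        best_pcs=pcs, seed=seed, rmsecv=score,
        extras={"q_init": int(q_init), "theta": theta, "eta": eta},
    )


def select(
    method: str, X: np.ndarray, y: np.ndarray, seed: int = 0, **kwargs
) -> SelectionResult:
    """Dispatch by selector name ('full', 'spa', 'cars', 'frog')."""
    if method == "full":
        return full_selection(np.asarray(X).shape[1], seed)
    if method == "spa":
        return spa_select(X, y, seed=seed, **kwargs)
    if method == "cars":
        return cars_select(X, y, seed=seed, **kwargs)
    if method == "frog":
        return frog_select(X, y, seed=seed, **kwargs)
    raise ConfigError(f"unknown selector {method!r}")
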