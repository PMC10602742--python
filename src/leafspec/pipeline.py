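"""The model-comparison grid: ranges x pretreatments x selectors x models.

``run_grid`` reproduces the structure of the study's comparison tables: for
each of the three spectral ranges (Vis-NIR, SWIR, combined), each pretreatment
(SNV, SG first derivative, MSC), each wavelength selector (full bands, SPA,
CARS, random frog) and each regressor (PLS, LS-SVM), it trains on the shared
training split and reports test-set R^2, RMSE and RPD — 3 x 3 x 4 x 2 = 72
rows by default.

Leakage discipline: the train/test split and the CV fold plan are drawn once
per run; pretreatment statistics (the MSC reference), wavelength selection
and hyperparameter tuning see training rows only; test rows are touched only
by the final frozen transform and model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evaluation import evaluate, train_test_split
from .hypercube import SPECTRAL_RANGES, crop_to_range
from .preprocessing import SpectraMatrix, apply_state, preprocess
from .regression import (
    grid_search_lssvm,
    kfold_indices,
    lssvm_fit,
    lssvm_predict,
    pls_fit,
    pls_predict,
    select_pcs_cv,
)
from .selection import SelectionResult, select

__all__ = [
    "RunConfig",
    "FittedPipeline",
    "combine_cameras",
    "fit_pipeline",
    "run_grid",
    "GRID_COLUMNS",
]

GRID_COLUMNS = [
    "range_label", "pretreatment", "selector", "n_vars", "model",
    "pcs", "gamma", "sigma2", "r2", "rmse", "rpd", "rpd_class",
    "seed", "status", "best",
]


def combine_cameras(vnir: SpectraMatrix, swir: SpectraMatrix) -> SpectraMatrix:
    """Concatenate the two camera matrices into the full-span matrix.

    SWIR bands below 975 nm duplicate the top of the Vis-NIR axis and are
    dropped, leaving a strictly increasing wavelength axis across both
    cameras.
    """
    if vnir.n_samples != swir.n_samples:
        raise ConfigError("camera matrices must describe the same samples")
    keep = swir.wavelengths >= 975.0
    wl = np.concatenate([vnir.wavelengths, swir.wavelengths[keep]])
    if not np.all(np.diff(wl) > 0):
        raise ConfigError("combined wavelength axis is not strictly increasing")
    return SpectraMatrix(
        np.hstack([vnir.values, swir.values[:, keep]]), wl, list(vnir.sample_ids)
    )


@dataclass
class RunConfig:
    """Everything one grid run depends on; serialized into every artifact."""

    split_ratio: float = 0.7
    split_seed: int = 0
    cv_folds: int = 10
    max_pcs: int = 30
    selector_max_pcs: int = 10
    spa_k_min: int = 2
    spa_k_max: int = 25
    cars_runs: int = 1000
    cars_mc_fraction: float = 0.8
    frog_iters: int = 1000
    frog_top_k: int = 10
    sg_window: int = 7
    sg_polyorder: int = 2
    ranges: tuple[str, ...] = ("I", "II", "III")
    pretreatments: tuple[str, ...] = ("snv", "sg1", "msc")
    selectors: tuple[str, ...] = ("full", "spa", "cars", "frog")
    models: tuple[str, ...] = ("pls", "lssvm")
    gamma_grid: tuple[float, ...] | None = None
    sigma2_grid: tuple[float, ...] | None = None
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class FittedPipeline:
    """A frozen (pretreatment, selection, model) chain ready for prediction."""

    range_label: str
    pretreatment: str
    selector: str
    model_kind: str
    preprocess_state: object
    selection: SelectionResult
    model: object
    report: object = None
    extras: dict = field(default_factory=dict)

    @property
    def tag(self) -> str:
        pre = {"snv": "SNV", "sg1": "S.G. 1st derivative", "msc": "MSC",
               "none": "raw"}[self.pretreatment]
        sel = {"full": "Full bands", "spa": "SPA", "cars": "CARS",
               "frog": "Random frog"}[self.selector]
        mod = {"pls": "PLS", "lssvm": "LS-SVM"}[self.model_kind]
        return f"{self.range_label}: {pre} + {sel} + {mod}"

    def predict(self, X_full_range: np.ndarray) -> np.ndarray:
        proc = apply_state(self.preprocess_state, X_full_range)
        Xs = proc[:, self.selection.indices]
        if self.model_kind == "pls":
            return pls_predict(self.model, Xs)
        return lssvm_predict(self.model, Xs)


def _sg_kwargs(config: RunConfig) -> dict:
    return {"window": config.sg_window, "polyorder": config.sg_polyorder}


def _selector_kwargs(config: RunConfig, selector: str) -> dict:
    if selector == "spa":
        return {"k_min": config.spa_k_min, "k_max": config.spa_k_max,
                "folds": config.cv_folds, "max_pcs": config.selector_max_pcs}
    if selector == "cars":
        return {"n_runs": config.cars_runs, "mc_fraction": config.cars_mc_fraction,
                "folds": config.cv_folds, "max_pcs": config.selector_max_pcs}
    if selector == "frog":
        return {"n_iter": config.frog_iters, "top_k": config.frog_top_k,
                "folds": config.cv_folds, "max_pcs": config.selector_max_pcs}
    return {}


def fit_pipeline(
    spectra: SpectraMatrix,
    y: np.ndarray,
    range_label: str = "II",
    pretreatment: str = "snv",
    selector: str = "spa",
    model_kind: str = "lssvm",
    config: RunConfig | None = None,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
    selection: SelectionResult | None = None,
) -> FittedPipeline:
    """Train one (range, pretreatment, selector, model) combination.

    ``spectra`` must already cover the requested range's cameras (use
    :func:`combine_cameras` for Range III).  If a split is not supplied the
    config's ratio/seed draw one.  A precomputed ``selection`` (shared
    between the PLS and LS-SVM rows of the grid) can be passed in.
    """
    config = config or RunConfig()
    y = np.asarray(y, dtype=float).ravel()
    rng_def = SPECTRAL_RANGES[range_label]
    trimmed = crop_to_range(spectra, rng_def)
    if train_idx is None or test_idx is None:
        train_idx, test_idx = train_test_split(
            trimmed.n_samples, config.split_ratio, config.split_seed
        )
    Xtr_p, state = preprocess(
        trimmed.take_rows(train_idx), pretreatment,
        **(_sg_kwargs(config) if pretreatment == "sg1" else {}),
    )
    Xtr = Xtr_p.values
    ytr = y[train_idx]
    Xte = apply_state(state, trimmed.values[test_idx])
    yte = y[test_idx]

    if selection is None:
        selection = select(
            selector, Xtr, ytr, seed=config.split_seed,
            **_selector_kwargs(config, selector),
        )
    Xtr_s = Xtr[:, selection.indices]
    Xte_s = Xte[:, selection.indices]

    fold_plan = kfold_indices(len(train_idx), config.cv_folds, config.split_seed)
    extras: dict = {}
    if model_kind == "pls":
        pcs, cv_rmse = select_pcs_cv(
            Xtr_s, ytr, max_pcs=config.max_pcs, fold_plan=fold_plan
        )
        model = pls_fit(Xtr_s, ytr, pcs)
        y_hat = pls_predict(model, Xte_s)
        extras = {"pcs": model.n_components, "cv_rmse": cv_rmse}
    elif model_kind == "lssvm":
        gkw = {}
        if config.gamma_grid is not None:
            gkw["gamma_grid"] = config.gamma_grid
        if config.sigma2_grid is not None:
            gkw["sigma2_grid"] = config.sigma2_grid
        gamma, sigma2, cv_rmse = grid_search_lssvm(
            Xtr_s, ytr, fold_plan=fold_plan, **gkw
        )
        model = lssvm_fit(Xtr_s, ytr, gamma, sigma2)
        y_hat = lssvm_predict(model, Xte_s)
        extras = {"gamma": gamma, "sigma2": sigma2, "cv_rmse": cv_rmse}
    else:
        raise ConfigError(f"unknown model {model_kind!r}")

    report = evaluate(yte, y_hat)
    return FittedPipeline(
        range_label=range_label, pretreatment=pretreatment, selector=selector,
        model_kind=model_kind, preprocess_state=state, selection=selection,
        model=model, report=report, extras=extras,
    )


def run_grid(
    vnir: SpectraMatrix,
    swir: SpectraMatrix,
    y: np.ndarray,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Evaluate every combination on one shared split; one row per combination.

    A failing combination yields a row with status='failed' rather than
    aborting the run.  The best successful row (max R^2, ties -> max RPD) is
    flagged in the ``best`` column.  With ``config.out_dir`` set, the table
    (CSV + JSON) and the run config are written there; outputs carry no
    timestamps so a rerun with the same inputs is byte-identical.
    """
    config = config or RunConfig()
    y = np.asarray(y, dtype=float).ravel()
    if vnir.n_samples != swir.n_samples or vnir.n_samples != y.size:
        raise ConfigError("vnir, swir and y must agree on sample count")
    matrices = {"I": vnir, "II": swir, "III": combine_cameras(vnir, swir)}
    train_idx, test_idx = train_test_split(
        y.size, config.split_ratio, config.split_seed
    )
    rows = []
    for range_label in config.ranges:
        spectra = matrices[range_label]
        for pretreatment in config.pretreatments:
            for selector in config.selectors:
                shared_selection = None
                for model_kind in config.models:
                    row = {
                        "range_label": SPECTRAL_RANGES[range_label].label,
                        "pretreatment": pretreatment,
                        "selector": selector,
                        "model": model_kind,
                        "seed": config.split_seed,
                        "n_vars": np.nan, "pcs": np.nan,
                        "gamma": np.nan, "sigma2": np.nan,
                        "r2": np.nan, "rmse": np.nan, "rpd": np.nan,
                        "rpd_class": "", "status": "ok", "best": False,
                    }
                    try:
                        fitted = fit_pipeline(
                            spectra, y, range_label, pretreatment, selector,
                            model_kind, config, train_idx, test_idx,
                            selection=shared_selection,
                        )
                        shared_selection = fitted.selection
                        rep = fitted.report
                        row.update(
                            n_vars=fitted.selection.n_selected,
                            r2=rep.r2, rmse=rep.rmse, rpd=rep.rpd,
                            rpd_class=rep.rpd_class,
                        )
                        if model_kind == "pls":
                            row["pcs"] = fitted.extras["pcs"]
                        else:
                            row["gamma"] = fitted.extras["gamma"]
                            row["sigma2"] = fitted.extras["sigma2"]
                    except Exception as exc:  # noqa: BLE001 - failure isolation
                        row["status"] = f"failed: {type(exc).__name__}: {exc}"
                    rows.append(row)
    result = pd.DataFrame(rows, columns=GRID_COLUMNS)
    ok = result[result["status"] == "ok"]
    if len(ok):
        best_i = ok.sort_values(
            ["r2", "rpd"], ascending=False, kind="stable"
        ).index[0]
        result.loc[best_i, "best"] = True
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        result.to_csv(os.path.join(config.out_dir, "grid_results.csv"), index=False)
        with open(os.path.join(config.out_dir, "grid_results.json"), "w") as f:
            json.dump(
                {"config": config.to_dict(), "config_digest": config.digest(),
                 "rows": result.to_dict(orient="records")},
                f, indent=2, default=float,
            )
    return result
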