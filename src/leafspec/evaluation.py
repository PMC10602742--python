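"""Data splitting, prediction metrics, and the Kjeldahl reference assay.

Model quality on the held-out test set is summarized by three numbers:

* R^2 — the coefficient of determination 1 - SS_res/SS_tot (not a squared
  correlation);
* RMSE — root mean squared prediction error, here in g protein / 100 g;
* RPD — ratio of the reference values' sample standard deviation (n-1) to
  the RMSE.  RPD < 1.4 means the model fails, 1.4 <= RPD < 2 supports rough
  screening ("average"), RPD >= 2 indicates excellent predictive power.

Reference protein values come from a Kjeldahl nitrogen titration: measured
nitrogen is converted to protein with the conventional factor F = 6.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "EvalReport",
    "KjeldahlAssay",
    "train_test_split",
    "r2",
    "rmse",
    "rpd",
    "rpd_class",
    "evaluate",
    "kjeldahl_protein",
]


def train_test_split(n: int, ratio: float = 0.7, seed: int = 0):
    """Random disjoint, exhaustive split of range(n).

    The training size is round(ratio*n) with half-up rounding, so n = 193 at
    ratio 0.7 gives the 135/58 split used throughout.
    """
    if n < 2:
        raise ConfigError(f"need at least 2 samples to split, got {n}")
    if not 0 < ratio < 1:
        raise ConfigError(f"ratio must be in (0, 1), got {ratio}")
    n_train = int(math.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _pair(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size or y.size == 0:
        raise ConfigError("y and y_hat must be non-empty and the same length")
    return y, y_hat


def r2(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y, y_hat = _pair(y, y_hat)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ConfigError("R^2 undefined for constant y")
    return 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot


def rmse(y, y_hat) -> float:
    y, y_hat = _pair(y, y_hat)
    return float(np.sqrt(((y - y_hat) ** 2).mean()))


def rpd(y, y_hat) -> float:
    """Sample standard deviation of y (n-1) over RMSE."""
    y, y_hat = _pair(y, y_hat)
    e = rmse(y, y_hat)
    if e == 0:
        raise ConfigError("RPD undefined when RMSE is 0")
    return float(np.std(y, ddof=1)) / e


def rpd_class(value: float) -> str:
    """fail (< 1.4), average (1.4 <= RPD < 2), excellent (>= 2)."""
    if value < 1.4:
        return "fail"
    if value < 2.0:
        return "average"
    return "excellent"


@dataclass
class EvalReport:
    r2: float
    rmse: float
    rpd: float
    rpd_class: str
    n_test: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "rpd": self.rpd,
            "rpd_class": self.rpd_class, "n_test": self.n_test,
        }


def evaluate(y, y_hat) -> EvalReport:
    """Bundle R^2 / RMSE / RPD (+ class) for a test set."""
    y, y_hat = _pair(y, y_hat)
    e = rmse(y, y_hat)
    d = rpd(y, y_hat)
    return EvalReport(r2=r2(y, y_hat), rmse=e, rpd=d, rpd_class=rpd_class(d),
                      n_test=int(y.size))


@dataclass
class KjeldahlAssay:
    """Titration record for one sample.

    V1/V2 are the sample and blank HCl volumes (mL), V3 the extracted-liquid
    volume (mL), C the HCl concentration (mol/L), m the dry sample mass (g),
    and F the nitrogen-to-protein conversion factor.
    """

    V1: float
    V2: float
    V3: float = 50.0
    C: float = 0.05
    m: float = 0.3
    F: float = 6.25

    def __post_init__(self) -> None:
        if self.V1 < self.V2:
            raise ConfigError("titration volume V1 must be >= blank V2")
        if self.m <= 0 or self.V3 <= 0:
            raise ConfigError("sample mass m and volume V3 must be positive")


def kjeldahl_protein(assay: KjeldahlAssay) -> float:
    """Protein content X (g/100 g) from a titration record.

    X = (V1 - V2) * C * 0.0140 * F * 100 / (m * V3/100): the titration
    difference times HCl concentration gives moles of nitrogen, 0.0140 g/mmol
    converts to grams of N, F converts N to protein, and the denominator
    scales by sample mass and the aliquot fraction V3/100.
    """
    denom = assay.m * assay.V3 / 100.0
    if denom <= 0:
        raise ConfigError("nonpositive denominator in Kjeldahl formula")
    return (assay.V1 - assay.V2) * assay.C * 0.0140 * assay.F * 100.0 / denom
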