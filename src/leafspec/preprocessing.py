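"""Row-wise spectral pretreatments: SNV, MSC, and Savitzky-Golay derivative.

All three operate on a :class:`SpectraMatrix` (samples x bands) and return the
transformed matrix together with a :class:`PreprocessState`.  The state makes
the transform reusable on spectra the training set never saw (test rows,
single pixels): SNV and the SG derivative are per-row self-contained, while
MSC regresses every row against a *reference* spectrum that is estimated once
from the training set and frozen into the state — re-estimating it on test or
pixel spectra would leak information and make pixel maps ill-defined.

Pretreatment is applied to the full trimmed spectral range before any
wavelength subsetting: SNV/MSC statistics are whole-spectrum quantities, so
selected-band indices always refer to columns of the preprocessed full-range
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, PreprocessError

__all__ = [
    "SpectraMatrix",
    "PreprocessState",
    "snv",
    "msc",
    "sg_first_derivative",
    "preprocess",
    "apply_state",
]

METHODS = ("none", "snv", "msc", "sg1")


@dataclass
class SpectraMatrix:
    """Samples x bands table with its wavelength axis (nm) and sample ids."""

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.shape[1] != self.wavelengths.size:
            raise ConfigError(
                f"{self.values.shape[1]} columns but {self.wavelengths.size} wavelengths"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ConfigError("sample_ids length does not match row count")
        if not np.isfinite(self.values).all():
            raise ConfigError("SpectraMatrix must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def take_rows(self, idx) -> "SpectraMatrix":
        return SpectraMatrix(
            self.values[idx], self.wavelengths.copy(),
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
        )


@dataclass
class PreprocessState:
    """Frozen description of a fitted pretreatment.

    ``msc_reference`` is present iff ``method == 'msc'``.  The SG derivative
    is taken with respect to band index (recorded here so that downstream
    users know the units are reflectance per band, not per nm).
    """

    method: str = "none"
    msc_reference: np.ndarray | None = None
    sg_window: int = 7
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method == "msc" and self.msc_reference is None:
            raise ConfigError("msc state requires a reference spectrum")
        if self.method == "sg1":
            _check_sg(self.sg_window, self.sg_polyorder)


def _check_sg(window: int, polyorder: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ConfigError(f"SG window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ConfigError(f"SG polyorder {polyorder} must be < window {window}")


def _rows(x) -> np.ndarray:
    arr = x.values if isinstance(x, SpectraMatrix) else np.atleast_2d(np.asarray(x, float))
    return arr


def snv(spectra: SpectraMatrix) -> tuple[SpectraMatrix, PreprocessState]:
    """Standard normal variate: each row to mean 0, sample sd 1 (n-1)."""
    out = _snv_values(_rows(spectra), spectra.sample_ids)
    return replace(spectra, values=out), PreprocessState(method="snv")


def _snv_values(X: np.ndarray, sample_ids=None) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = sd.ravel() <= 0
    if flat.any():
        ids = (
            [sample_ids[i] for i in np.flatnonzero(flat)]
            if sample_ids is not None
            else list(np.flatnonzero(flat))
        )
        raise PreprocessError(f"SNV undefined for constant spectra: {ids}")
    return (X - mu) / sd


def msc(
    spectra: SpectraMatrix, reference: np.ndarray | None = None
) -> tuple[SpectraMatrix, PreprocessState]:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is modelled as x = a + b*ref; the corrected row is (x - a)/b.
    The reference defaults to the column mean of the input (the training set)
    and is frozen into the returned state.
    """
    X = _rows(spectra)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.size != X.shape[1]:
        raise ConfigError("MSC reference length does not match band count")
    out = _msc_values(X, ref, spectra.sample_ids)
    state = PreprocessState(method="msc", msc_reference=ref.copy())
    return replace(spectra, values=out), state


def _msc_values(X: np.ndarray, ref: np.ndarray, sample_ids=None) -> np.ndarray:
    # Per-row least squares x ~ a + b*ref, all rows at once.
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0:
        raise PreprocessError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = X.mean(axis=1) - b * ref.mean()
    bad = np.abs(b) <= 1e-8
    if bad.any():
        ids = (
            [sample_ids[i] for i in np.flatnonzero(bad)]
            if sample_ids is not None
            else list(np.flatnonzero(bad))
        )
        raise PreprocessError(f"MSC slope ~ 0 for samples: {ids}")
    return (X - a[:, None]) / b[:, None]


def sg_first_derivative(
    spectra: SpectraMatrix, window: int = 7, polyorder: int = 2
) -> tuple[SpectraMatrix, PreprocessState]:
    """Savitzky-Golay first derivative along the wavelength axis.

    A local polynomial of the given order is least-squares fitted in each
    window and differentiated at its centre; edge values come from one-sided
    fits on the first/last windows.  The derivative is with respect to band
    index (bands are uniformly spaced on the synthetic grids, so this is
    proportional to d/dnm).
    """
    _check_sg(window, polyorder)
    X = _rows(spectra)
    if window > X.shape[1]:
        raise ConfigError(f"SG window {window} exceeds band count {X.shape[1]}")
    out = savgol_filter(X, window, polyorder, deriv=1, delta=1.0, axis=1, mode="interp")
    state = PreprocessState(method="sg1", sg_window=window, sg_polyorder=polyorder)
    return replace(spectra, values=out), state


def preprocess(
    spectra: SpectraMatrix, method: str, **kwargs
) -> tuple[SpectraMatrix, PreprocessState]:
    """Fit-and-apply one of the named pretreatments on (training) spectra."""
    if method == "none":
        return replace(spectra, values=spectra.values.copy()), PreprocessState()
    if method == "snv":
        return snv(spectra)
    if method == "msc":
        return msc(spectra, kwargs.get("reference"))
    if method == "sg1":
        return sg_first_derivative(
            spectra, kwargs.get("window", 7), kwargs.get("polyorder", 2)
        )
    raise ConfigError(f"unknown pretreatment {method!r}")


def apply_state(state: PreprocessState, X: np.ndarray) -> np.ndarray:
    """Apply a fitted pretreatment to new spectra (test rows, pixel spectra).

    ``X`` is samples x bands on the same trimmed wavelength grid the state was
    fitted on.  Rows for which the transform is undefined (e.g. a constant
    spectrum under SNV) raise PreprocessError; callers that must survive bad
    pixels should catch it per row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if state.method == "none":
        return X.copy()
    if state.method == "snv":
        return _snv_values(X)
    if state.method == "msc":
        return _msc_values(X, state.msc_reference)
    if state.method == "sg1":
        return savgol_filter(
            X, state.sg_window, state.sg_polyorder, deriv=1, delta=1.0,
            axis=1, mode="interp",
        )
    raise ConfigError(f"unknown pretreatment {state.method!r}")
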