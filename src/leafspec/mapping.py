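"""Pixel-wise constituent prediction over a leaf mask and map rendering.

A trained pipeline (pretreatment state + selected bands + regression model)
is applied to the full-range spectrum of every foreground pixel, producing a
protein map in g/100 g with NaN outside the mask.  The per-pixel order
mirrors training exactly: preprocess the whole trimmed spectrum first, then
subset to the selected bands, then predict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, PreprocessError
from .hypercube import Hypercube
from .preprocessing import PreprocessState, apply_state
from .regression import LSSVMModel, PLSModel, lssvm_predict, pls_predict
from .selection import SelectionResult

__all__ = ["ProteinMap", "predict_pixel_map", "render_map"]


@dataclass
class ProteinMap:
    """Per-pixel predicted constituent values; NaN marks no-data."""

    values: np.ndarray
    mask: np.ndarray
    model_tag: str = ""
    n_failed_pixels: int = 0
    extras: dict = field(default_factory=dict)

    def foreground_values(self) -> np.ndarray:
        v = self.values[self.mask]
        return v[np.isfinite(v)]


def _model_predict(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, PLSModel):
        return pls_predict(model, X)
    if isinstance(model, LSSVMModel):
        return lssvm_predict(model, X)
    raise ConfigError(f"unsupported model type {type(model).__name__}")


def predict_pixel_map(
    cube: Hypercube,
    mask: np.ndarray,
    preprocess_state: PreprocessState,
    selection: SelectionResult,
    model,
    model_tag: str = "",
) -> ProteinMap:
    """Predict a constituent value for every foreground pixel.

    ``cube`` must already be trimmed to the spectral range the model was
    trained on; ``preprocess_state`` is the frozen training-set state (for
    MSC this pins the reference spectrum).  Pixels whose pretreatment fails
    (e.g. a constant spectrum under SNV) or that contain non-finite
    reflectance become no-data and are counted in ``n_failed_pixels``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ConfigError("mask shape does not match cube")
    spectra = cube.data[mask]  # n_fg x bands
    n_fg = spectra.shape[0]
    preds = np.full(n_fg, np.nan)
    finite = np.isfinite(spectra).all(axis=1)
    n_failed = int((~finite).sum())
    if finite.any():
        try:
            proc = apply_state(preprocess_state, spectra[finite])
            preds[finite] = _model_predict(model, proc[:, selection.indices])
        except PreprocessError:
            # Retry pixel by pixel so one bad spectrum cannot void the map.
            idx = np.flatnonzero(finite)
            for i in idx:
                try:
                    proc = apply_state(preprocess_state, spectra[i : i + 1])
                    preds[i] = _model_predict(model, proc[:, selection.indices])[0]
                except PreprocessError:
                    n_failed += 1
    values = np.full(mask.shape, np.nan)
    values[mask] = preds
    return ProteinMap(values=values, mask=mask, model_tag=model_tag,
                      n_failed_pixels=n_failed)


def render_map(
    pmap: ProteinMap,
    out_path: str,
    vmin: float | None = None,
    vmax: float | None = None,
    cmap: str = "viridis",
    unit_label: str = "protein (g/100 g)",
) -> None:
    """Write an 8-bit color-mapped PNG with a value legend.

    ``vmin``/``vmax`` default to the map's own finite range, but passing the
    training-set constituent range keeps the shading comparable across
    leaves.  No-data pixels render as a neutral light gray.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fg = pmap.foreground_values()
    if fg.size == 0:
        raise ConfigError("map has no finite foreground values to render")
    vmin = float(fg.min()) if vmin is None else vmin
    vmax = float(fg.max()) if vmax is None else vmax
    if vmax <= vmin:
        vmax = vmin + 1e-9
    fig, ax = plt.subplots(figsize=(5, 4))
    cm = matplotlib.colormaps[cmap].copy()
    cm.set_bad("0.85")
    im = ax.imshow(np.ma.masked_invalid(pmap.values), cmap=cm, vmin=vmin, vmax=vmax)
    fig.colorbar(im, ax=ax, label=unit_label)
    if pmap.model_tag:
        ax.set_title(pmap.model_tag, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
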