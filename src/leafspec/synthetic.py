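"""Synthetic leaf hyperspectral data with known ground truth.

No public dataset accompanies the protein-prediction problem this package
addresses, so every stage is exercised on simulated data whose statistical
structure matches what the analysis assumes:

* two camera wavelength grids — Vis-NIR 423-975 nm and SWIR 970-1684 nm,
  204 uniformly spaced bands each;
* a green-vegetation baseline reflectance curve (green peak near 555 nm, red
  valley near 660 nm, steep red edge onto a high NIR plateau, water
  absorption dip near 1450 nm);
* protein-dependent absorption: reflectance is depressed around a handful of
  absorption centres in proportion to protein content, so higher-protein
  leaves are darker at those wavelengths;
* multiplicative/additive scatter (per-spectrum gain and offset) plus white
  band noise — exactly the distortions SNV and MSC are meant to remove;
* leaf-shaped image masks with a midrib and branching veins whose protein is
  a fixed fraction of the blade's, for pixel-map ground truth;
* Kjeldahl-style reference values obtained by inverting the titration
  formula, perturbing, and recomputing protein through it.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evaluation import KjeldahlAssay, kjeldahl_protein
from .hypercube import Hypercube
from .preprocessing import SpectraMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "camera_grid",
    "baseline_leaf_spectrum",
    "generate_spectra",
    "generate_two_camera_spectra",
    "generate_leaf_cube",
    "generate_references",
]

_CAMERA_SPANS = {"VNIR": (423.0, 975.0), "SWIR": (970.0, 1684.0)}

#: Default protein-absorption centres per camera (nm).  The SWIR pair sits in
#: the regions where N-H-related features concentrate (1170-1350 nm and the
#: 1460-1570 nm overtone region); the VNIR pair reflects pigment-linked
#: covariation in the green/red region.
_DEFAULT_CENTRES = {"VNIR": (560.0, 660.0), "SWIR": (1180.0, 1510.0)}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions.

    ``beta`` is the fractional reflectance depression per (g/100 g) of
    protein at an absorption centre; with the default protein range 10-46
    the depression spans 12-55 %, comfortably away from non-physical
    negative reflectance.
    """

    camera: str = "SWIR"
    n_bands: int = 204
    n_samples: int = 193
    protein_range: tuple[float, float] = (10.0, 46.0)
    absorption_centres: tuple[float, ...] | None = None
    absorption_width: float = 30.0
    beta: float = 0.012
    gain_sd: float = 0.05
    offset_sd: float = 0.01
    noise_sd: float = 0.003
    vein_protein_factor: float = 0.35
    spatial_field_sd: float = 0.8
    pixel_gain_sd: float = 0.02
    image_size: tuple[int, int] = (80, 100)
    background_reflectance: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.camera not in ("VNIR", "SWIR", "BOTH"):
            raise ConfigError("camera must be VNIR, SWIR or BOTH")
        if self.n_bands < 2 or self.n_samples < 2:
            raise ConfigError("need at least 2 bands and 2 samples")
        lo, hi = self.protein_range
        if not hi > lo:
            raise ConfigError("protein_range hi must exceed lo")
        if min(self.gain_sd, self.offset_sd, self.noise_sd) < 0:
            raise ConfigError("noise scales must be >= 0")
        if not 0 < self.vein_protein_factor < 1:
            raise ConfigError("vein_protein_factor must be in (0, 1)")

    def centres_for(self, camera: str) -> np.ndarray:
        if self.absorption_centres is not None:
            lo, hi = _CAMERA_SPANS[camera]
            return np.array(
                [c for c in self.absorption_centres if lo <= c <= hi], dtype=float
            )
        return np.array(_DEFAULT_CENTRES[camera], dtype=float)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    protein_per_sample: np.ndarray | None = None
    protein_map: np.ndarray | None = None
    informative_band_indices: np.ndarray | None = None
    informative_centres_nm: np.ndarray | None = None
    true_mask: np.ndarray | None = None
    vein_mask: np.ndarray | None = None
    clean_spectra: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def camera_grid(camera: str, n_bands: int = 204) -> np.ndarray:
    """Uniform band-centre grid over the camera's trimmed span."""
    try:
        lo, hi = _CAMERA_SPANS[camera]
    except KeyError:
        raise ConfigError(f"unknown camera {camera!r}") from None
    return np.linspace(lo, hi, n_bands)


def baseline_leaf_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth green-vegetation reflectance baseline in (0, 1).

    Sum of a logistic red-edge rise onto the NIR plateau, a Gaussian green
    peak at 555 nm, a shallow red dip at 660 nm and a water-absorption dip at
    1450 nm, over a small floor.  Constants are fixed here (not exposed): the
    curve only needs the qualitative ordering green peak > red valley and
    NIR plateau > visible floor.
    """
    wl = np.asarray(wavelengths, dtype=float)
    red_edge = 0.55 / (1.0 + np.exp(-(wl - 705.0) / 15.0))
    green = 0.15 * np.exp(-((wl - 555.0) ** 2) / (2 * 28.0**2))
    red_dip = -0.05 * np.exp(-((wl - 660.0) ** 2) / (2 * 25.0**2))
    water = -0.28 * np.exp(-((wl - 1450.0) ** 2) / (2 * 45.0**2))
    return 0.08 + red_edge + green + red_dip + water


def _absorption_profile(wl: np.ndarray, centres: np.ndarray, width: float) -> np.ndarray:
    """Sum of unit-height Gaussians at the protein absorption centres."""
    if centres.size == 0:
        return np.zeros_like(wl)
    return np.exp(
        -((wl[None, :] - centres[:, None]) ** 2) / (2 * width**2)
    ).sum(axis=0)


def clean_spectrum(
    wavelengths: np.ndarray, protein, config: SyntheticConfig, camera: str
) -> np.ndarray:
    """Noise-free reflectance for given protein value(s): rows per sample."""
    wl = np.asarray(wavelengths, dtype=float)
    p = np.atleast_1d(np.asarray(protein, dtype=float))
    prof = _absorption_profile(wl, config.centres_for(camera), config.absorption_width)
    depress = config.beta * p[:, None] * prof[None, :]
    if (depress >= 1.0).any():
        raise ConfigError(
            "beta * protein * absorption overlap >= 1 implies negative reflectance"
        )
    return baseline_leaf_spectrum(wl)[None, :] * (1.0 - depress)


def _informative_indices(wl: np.ndarray, centres: np.ndarray) -> np.ndarray:
    return np.array([int(np.argmin(np.abs(wl - c))) for c in centres], dtype=int)


def _observe(clean: np.ndarray, rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    n, b = clean.shape
    gain = rng.normal(1.0, cfg.gain_sd, size=(n, 1))
    offset = rng.normal(0.0, cfg.offset_sd, size=(n, 1))
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, b))
    return gain * clean + offset + noise


def generate_spectra(config: SyntheticConfig) -> tuple[SpectraMatrix, GroundTruth]:
    """Sample-level mean spectra for one camera (or both concatenated).

    Protein is uniform over ``protein_range``; each sample's clean spectrum
    is the baseline depressed at the absorption centres in proportion to
    protein, observed through per-spectrum gain/offset scatter and band
    noise.  With camera='BOTH' the VNIR and SWIR matrices (same protein,
    independent scatter) are concatenated on the wavelength axis.
    """
    if config.camera == "BOTH":
        vnir, swir, truth = generate_two_camera_spectra(config)
        values = np.hstack([vnir.values, swir.values])
        wl = np.concatenate([vnir.wavelengths, swir.wavelengths])
        # The concatenated axis is not strictly increasing in the 970-975 nm
        # overlap; SpectraMatrix does not require it, range cropping does —
        # use combine_cameras (pipeline module) for a clean Range III matrix.
        sm = SpectraMatrix(values, wl, vnir.sample_ids)
        return sm, truth
    rng = np.random.default_rng(config.seed)
    wl = camera_grid(config.camera, config.n_bands)
    lo, hi = config.protein_range
    protein = rng.uniform(lo, hi, size=config.n_samples)
    clean = clean_spectrum(wl, protein, config, config.camera)
    observed = _observe(clean, rng, config)
    sm = SpectraMatrix(observed, wl)
    centres = config.centres_for(config.camera)
    truth = GroundTruth(
        protein_per_sample=protein,
        informative_band_indices=_informative_indices(wl, centres),
        informative_centres_nm=centres,
        clean_spectra=clean,
    )
    return sm, truth


def generate_two_camera_spectra(
    config: SyntheticConfig,
) -> tuple[SpectraMatrix, SpectraMatrix, GroundTruth]:
    """VNIR and SWIR matrices for the same physical samples.

    Protein values are shared; scatter and noise are drawn independently per
    camera, as two separate acquisitions would produce.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_range
    protein = rng.uniform(lo, hi, size=config.n_samples)
    mats, cleans, idx, centres_all = {}, {}, {}, {}
    for camera in ("VNIR", "SWIR"):
        wl = camera_grid(camera, config.n_bands)
        clean = clean_spectrum(wl, protein, config, camera)
        mats[camera] = SpectraMatrix(_observe(clean, rng, config), wl)
        cleans[camera] = clean
        centres = config.centres_for(camera)
        centres_all[camera] = centres
        idx[camera] = _informative_indices(wl, centres)
    truth = GroundTruth(
        protein_per_sample=protein,
        informative_band_indices=idx["SWIR"],
        informative_centres_nm=centres_all["SWIR"],
        extras={
            "informative_band_indices_vnir": idx["VNIR"],
            "informative_centres_nm_vnir": centres_all["VNIR"],
            "clean_spectra_vnir": cleans["VNIR"],
            "clean_spectra_swir": cleans["SWIR"],
        },
    )
    return mats["VNIR"], mats["SWIR"], truth


# ---------------------------------------------------------------------------
# Leaf image cubes
# ---------------------------------------------------------------------------


def _leaf_geometry(rows: int, cols: int):
    """Elliptical blade mask plus midrib and branching vein masks."""
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    a, b = 0.40 * rows, 0.45 * cols  # semi-axes; blade elongated along cols
    inside = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    vein = np.zeros((rows, cols), dtype=bool)
    # Midrib along the major (column) axis.
    vein |= np.abs(rr - r0) <= 1.0
    # Branch veins leaving the midrib at alternating diagonal angles.
    n_branches = 6
    for k in range(n_branches):
        ck = c0 + (k - (n_branches - 1) / 2.0) * (2 * b / n_branches)
        slope = 0.7 if k % 2 == 0 else -0.7
        vein |= np.abs((rr - r0) - slope * (cc - ck)) <= 1.0
    vein &= inside
    return inside, vein


def generate_leaf_cube(
    config: SyntheticConfig,
) -> tuple[Hypercube, Hypercube, Hypercube, GroundTruth]:
    """Raw, white and dark cubes for one leaf, plus full ground truth.

    The leaf is an ellipse with a midrib and branching veins; vein pixels
    carry ``vein_protein_factor`` times the blade protein, and a smooth
    low-amplitude spatial field adds within-leaf variation.  White counts
    follow a smooth illumination profile, dark counts a low pedestal, and
    the raw cube is assembled exactly as dark + reflectance * (white - dark),
    so calibration inverts the construction to machine precision.
    """
    if config.camera == "BOTH":
        raise ConfigError("generate_leaf_cube needs a single camera (VNIR or SWIR)")
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_size
    wl = camera_grid(config.camera, config.n_bands)
    nb = wl.size
    inside, vein = _leaf_geometry(rows, cols)

    lo, hi = config.protein_range
    blade_protein = float(rng.uniform(lo, hi))
    field2d = config.spatial_field_sd * (
        np.cos(2 * np.pi * np.arange(rows)[:, None] / rows)
        * np.cos(2 * np.pi * np.arange(cols)[None, :] / cols)
    )
    pmap = np.where(vein, blade_protein * config.vein_protein_factor, blade_protein)
    pmap = np.clip(pmap + field2d, 0.0, None)
    pmap = np.where(inside, pmap, np.nan)

    refl = np.empty((rows, cols, nb))
    bg = config.background_reflectance
    refl[~inside] = bg
    leaf_clean = clean_spectrum(wl, pmap[inside], config, config.camera)
    refl[inside] = leaf_clean
    gain = rng.normal(1.0, config.pixel_gain_sd, size=(rows, cols, 1))
    noise = rng.normal(0.0, config.noise_sd, size=(rows, cols, nb))
    refl = gain * refl + noise

    illum = 1.0 + 0.08 * np.cos(np.pi * (np.arange(cols) - (cols - 1) / 2) / cols)
    white_counts = 4000.0 * illum[None, :, None] * np.ones((rows, 1, nb))
    dark_counts = 100.0 + 5.0 * np.cos(
        2 * np.pi * np.arange(cols) / cols
    )[None, :, None] * np.ones((rows, 1, nb))
    raw_counts = dark_counts + refl * (white_counts - dark_counts)

    label = config.camera
    raw = Hypercube(raw_counts, wl, "raw", label)
    white = Hypercube(white_counts, wl, "white", label)
    dark = Hypercube(dark_counts, wl, "dark", label)
    centres = config.centres_for(config.camera)
    truth = GroundTruth(
        protein_per_sample=np.array([blade_protein]),
        protein_map=pmap,
        informative_band_indices=_informative_indices(wl, centres),
        informative_centres_nm=centres,
        true_mask=inside,
        vein_mask=vein,
        extras={"reflectance": refl},
    )
    return raw, white, dark, truth


# ---------------------------------------------------------------------------
# Reference assay values
# ---------------------------------------------------------------------------

def generate_references(
    ground_truth: GroundTruth,
    assay_noise_sd: float = 0.3,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Kjeldahl-style reference table for the generated samples.

    True protein is perturbed with Gaussian assay noise, converted to a
    titration difference by inverting the Kjeldahl formula at the default
    assay constants (C=0.05 mol/L, m=0.3 g, V3=50 mL, F=6.25, blank
    V2=0.2 mL), and the reported protein is recomputed through the forward
    formula — so the table is internally consistent to machine precision.
    """
    truth = np.asarray(ground_truth.protein_per_sample, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = np.clip(truth + rng.normal(0.0, assay_noise_sd, truth.size), 0.0, None)
    C, m, V3, F, V2 = 0.05, 0.3, 50.0, 6.25, 0.2
    factor = C * 0.0140 * F * 100.0 / (m * V3 / 100.0)  # X per mL of (V1-V2)
    rows = []
    ids = sample_ids or [f"S{i:03d}" for i in range(truth.size)]
    for sid, x in zip(ids, noisy):
        v1 = V2 + x / factor
        assay = KjeldahlAssay(V1=v1, V2=V2, V3=V3, C=C, m=m, F=F)
        rows.append(
            {"sample_id": sid, "protein_g_per_100g": kjeldahl_protein(assay),
             "V1": v1, "V2": V2, "V3": V3, "C": C, "m": m, "F": F}
        )
    return pd.DataFrame(rows)
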