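"""Hyperspectral cube data model, reflectance calibration and band arithmetic.

A :class:`Hypercube` holds a rows x cols x bands array together with its
wavelength axis (nm).  Cubes come in four kinds: ``raw`` sample scans,
``white``/``dark`` reference scans, and ``calibrated`` reflectance obtained as

    R = (I - D) / (W - D)

where I is the raw scan and W, D the white (~99 % reflectance board) and dark
(closed-shutter) references.  Pixels whose reference contrast W - D is at or
below a small counts-scale epsilon are marked invalid (NaN) rather than
divided, and downstream masking/averaging excludes them.

Two on-disk representations are supported: a minimal ENVI dialect (ASCII
``.hdr`` + little-endian raw binary, bil/bip/bsq interleaves) and a portable
HDF5 container with datasets ``/data`` and ``/wavelengths``.  In memory the
axis order is always rows x cols x bands regardless of on-disk interleave.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import h5py
import numpy as np

from .errors import CalibrationError, FormatError, RangeError, StructuralError

__all__ = [
    "Hypercube",
    "WavelengthRange",
    "SPECTRAL_RANGES",
    "DEGENERATE_EPS",
    "calibrate",
    "crop_to_range",
    "nearest_band",
    "read_cube",
    "write_cube",
]

#: Counts-scale threshold below which W - D is considered degenerate.
DEGENERATE_EPS = 1e-6

_KINDS = ("raw", "white", "dark", "calibrated")


@dataclass
class Hypercube:
    """A 3-D spectral image: ``data[row, col, band]`` with band centres in nm.

    ``data`` holds raw counts for raw/white/dark cubes and unitless
    reflectance for calibrated ones.  Calibrated values are deliberately not
    clipped to [0, 1]; specular highlights legitimately exceed 1 and clipping
    would distort SNV/MSC statistics computed later.  Invalid pixels are NaN.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"
    camera_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise StructuralError(f"cube data must be 3-D, got {self.data.ndim}-D")
        if self.data.shape[2] != self.wavelengths.size:
            raise StructuralError(
                f"{self.data.shape[2]} bands but {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise StructuralError("wavelength axis must be strictly increasing")
        if self.kind not in _KINDS:
            raise StructuralError(f"kind must be one of {_KINDS}, got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_image(self, target_nm: float) -> np.ndarray:
        """2-D slice at the band nearest ``target_nm``."""
        return self.data[:, :, nearest_band(self.wavelengths, target_nm)]


@dataclass(frozen=True)
class WavelengthRange:
    """Closed interval [lo, hi] in nm; endpoint band centres are included."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise StructuralError(f"range lo must be < hi, got ({self.lo}, {self.hi})")

    def contains(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths)
        return (wl >= self.lo) & (wl <= self.hi)


#: The three analysis ranges: Vis-NIR, SWIR, and both cameras combined.
SPECTRAL_RANGES: dict[str, WavelengthRange] = {
    "I": WavelengthRange(423.0, 975.0, "Spectral Range I"),
    "II": WavelengthRange(970.0, 1684.0, "Spectral Range II"),
    "III": WavelengthRange(423.0, 1684.0, "Spectral Range III"),
}


def calibrate(raw: Hypercube, white: Hypercube, dark: Hypercube) -> Hypercube:
    """Convert raw counts to reflectance via R = (I - D) / (W - D).

    Pixels (per band) where W - D <= DEGENERATE_EPS are set to NaN instead of
    being divided; if every pixel is degenerate calibration fails outright.
    """
    for cube, kind in ((raw, "raw"), (white, "white"), (dark, "dark")):
        if cube.kind != kind:
            raise StructuralError(f"expected a {kind!r} cube, got {cube.kind!r}")
    if not (raw.shape == white.shape == dark.shape):
        raise StructuralError(
            f"shape mismatch: raw {raw.shape}, white {white.shape}, dark {dark.shape}"
        )
    if not (
        np.array_equal(raw.wavelengths, white.wavelengths)
        and np.array_equal(raw.wavelengths, dark.wavelengths)
    ):
        raise StructuralError("raw/white/dark wavelength axes differ")

    denom = white.data - dark.data
    bad = denom <= DEGENERATE_EPS
    if bad.all():
        raise CalibrationError("white - dark is degenerate at every pixel")
    with np.errstate(invalid="ignore", divide="ignore"):
        refl = np.where(bad, np.nan, (raw.data - dark.data) / np.where(bad, 1.0, denom))
    return Hypercube(refl, raw.wavelengths.copy(), "calibrated", raw.camera_label)


def crop_to_range(obj, rng: WavelengthRange):
    """Keep exactly the bands with lo <= lambda <= hi (closed interval).

    Works on a :class:`Hypercube` or on any object exposing ``values``
    (samples x bands) and ``wavelengths`` with a ``replace``-style constructor
    (the SpectraMatrix of the preprocessing module).
    """
    keep = rng.contains(obj.wavelengths)
    if not keep.any():
        raise RangeError(
            f"no band centre in [{rng.lo}, {rng.hi}] nm "
            f"(axis spans {obj.wavelengths[0]:.1f}-{obj.wavelengths[-1]:.1f} nm)"
        )
    if isinstance(obj, Hypercube):
        return replace(
            obj, data=obj.data[:, :, keep], wavelengths=obj.wavelengths[keep]
        )
    return replace(
        obj, values=obj.values[:, keep], wavelengths=obj.wavelengths[keep]
    )


def nearest_band(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band centre closest to ``target_nm``; ties go to the
    lower index."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise StructuralError("empty wavelength axis")
    return int(np.argmin(np.abs(wl - target_nm)))


# ---------------------------------------------------------------------------
# I/O: portable HDF5 container and a minimal ENVI dialect
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
                12: np.uint16, 13: np.uint32}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_cube(cube: Hypercube, path: str, fmt: str = "h5", interleave: str = "bip") -> None:
    """Write a cube to ``path``.

    ``fmt='h5'`` writes the portable container (bit-exact round trip);
    ``fmt='envi'`` writes ``path + '.hdr'`` and raw little-endian binary at
    ``path`` in the requested interleave.
    """
    if fmt == "h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=cube.data)
            f.create_dataset("wavelengths", data=cube.wavelengths)
            f.attrs["kind"] = cube.kind
            f.attrs["camera_label"] = cube.camera_label
        return
    if fmt != "envi":
        raise FormatError(f"unknown cube format {fmt!r}")
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"interleave must be bil/bip/bsq, got {interleave!r}")
    rows, cols, bands = cube.shape
    arr = cube.data.astype("<f8")
    if interleave == "bip":        # lines x samples x bands
        ondisk = arr
    elif interleave == "bil":      # lines x bands x samples
        ondisk = arr.transpose(0, 2, 1)
    else:                          # bsq: bands x lines x samples
        ondisk = arr.transpose(2, 0, 1)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{leafspec cube, kind = {cube.kind}, "
        f"camera = {cube.camera_label}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype('float64')]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    with open(path + ".hdr", "w") as f:
        f.write(header)
    ondisk.tofile(path)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("missing ENVI magic line")
    # Collapse brace-delimited multi-line values, then split on key = value.
    fields: dict[str, str] = {}
    buf = ""
    for line in text.splitlines()[1:]:
        buf += line.strip() + " "
        if buf.count("{") == buf.count("}"):
            if "=" in buf:
                key, _, value = buf.partition("=")
                fields[key.strip().lower()] = value.strip()
            buf = ""
    return fields


def _read_envi(path: str) -> Hypercube:
    if path.endswith(".hdr"):
        hdr_path, data_path = path, path[: -len(".hdr")]
    else:
        hdr_path, data_path = path + ".hdr", path
    if not os.path.exists(hdr_path):
        raise FormatError(f"no ENVI header at {hdr_path}")
    with open(hdr_path) as f:
        fields = _parse_envi_header(f.read())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian (byte order = 0) is supported")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<")
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise FormatError(
            f"binary holds {raw.size} values, header promises {rows * cols * bands}"
        )
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().strip("{}")
        wavelengths = np.array([float(v) for v in wl_text.split(",") if v.strip()])
        if wavelengths.size != bands:
            raise FormatError(
                f"{wavelengths.size} wavelengths for {bands} bands in header"
            )
    else:
        wavelengths = np.arange(bands, dtype=float)
    kind, camera = "raw", ""
    desc = fields.get("description", "").strip("{} ")
    for part in desc.split(","):
        key, _, value = part.partition("=")
        if key.strip() == "kind" and value.strip() in _KINDS:
            kind = value.strip()
        if key.strip() == "camera":
            camera = value.strip()
    return Hypercube(np.ascontiguousarray(data, dtype=np.float64), wavelengths,
                     kind, camera)


def read_cube(path: str, fmt: str | None = None) -> Hypercube:
    """Read a cube written by :func:`write_cube` (or any conforming file).

    Format is inferred from the file when not given: HDF5 containers are
    detected by signature, anything else is treated as the ENVI dialect.
    """
    if fmt is None:
        fmt = "h5" if h5py.is_hdf5(path) else "envi"
    if fmt == "h5":
        with h5py.File(path, "r") as f:
            return Hypercube(
                f["data"][()],
                f["wavelengths"][()],
                str(f.attrs.get("kind", "raw")),
                str(f.attrs.get("camera_label", "")),
            )
    if fmt == "envi":
        return _read_envi(path)
    raise FormatError(f"unknown cube format {fmt!r}")
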