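"""CSV interchange for spectra tables and reference protein values."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError
from .preprocessing import SpectraMatrix

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_references_csv",
    "read_references_csv",
]


def write_spectra_csv(spectra: SpectraMatrix, path: str) -> None:
    """First column ``sample_id``, then one column per wavelength (nm)."""
    df = pd.DataFrame(
        spectra.values, columns=[f"{w:.6f}" for w in spectra.wavelengths]
    )
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path: str) -> SpectraMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise FormatError("spectra CSV must start with a sample_id column")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError("spectra CSV header columns must be wavelengths in nm") from exc
    return SpectraMatrix(
        df.iloc[:, 1:].to_numpy(dtype=float), wavelengths,
        df["sample_id"].astype(str).tolist(),
    )


def write_references_csv(refs: pd.DataFrame, path: str) -> None:
    refs.to_csv(path, index=False)


def read_references_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sample_id", "protein_g_per_100g"):
        if col not in df.columns:
            raise FormatError(f"references CSV missing column {col!r}")
    return df
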