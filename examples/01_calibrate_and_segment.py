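"""Reflectance calibration and Otsu leaf segmentation on a synthetic scan.

A raw leaf scan plus white/dark reference cubes are simulated, calibrated to
reflectance via R = (I - D)/(W - D), segmented at the 1000 nm gray band, and
reduced to one whole-leaf mean spectrum.
"""

import numpy as np

from leafspec import (
    SyntheticConfig,
    calibrate,
    generate_leaf_cube,
    mean_spectrum,
    segment_leaf,
)

raw, white, dark, truth = generate_leaf_cube(SyntheticConfig(camera="SWIR", seed=42))
print(f"raw cube: {raw.shape[0]}x{raw.shape[1]} pixels, {raw.n_bands} bands "
      f"({raw.wavelengths[0]:.0f}-{raw.wavelengths[-1]:.0f} nm)")

cal = calibrate(raw, white, dark)
err = np.nanmax(np.abs(cal.data - truth.extras["reflectance"]))
print(f"calibration error vs known reflectance: {err:.2e}")

mask = segment_leaf(cal, band_nm=1000.0)
jaccard = (mask & truth.true_mask).sum() / (mask | truth.true_mask).sum()
print(f"leaf mask: {int(mask.sum())} pixels, Jaccard vs ground truth {jaccard:.3f}")

spectrum = mean_spectrum(cal, mask)
j = int(np.argmin(np.abs(cal.wavelengths - 1180)))
print(f"mean reflectance at 1180 nm: {spectrum[j]:.3f} "
      f"(depressed by protein {truth.protein_per_sample[0]:.1f} g/100 g)")

# The calibration inverts the acquisition model to machine precision, the
# mask matches the planted leaf outline, and the 1180 nm reflectance carries
# the protein signal the later stages will exploit.
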