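"""The synthetic-data generator: spectral shape, noise model, ground truth."""

import numpy as np
import pytest

from leafspec import (
    ConfigError,
    SyntheticConfig,
    baseline_leaf_spectrum,
    calibrate,
    camera_grid,
    generate_leaf_cube,
    generate_references,
    generate_spectra,
    generate_two_camera_spectra,
    kjeldahl_protein,
    msc,
    snv,
)
from leafspec.evaluation import KjeldahlAssay
from leafspec.synthetic import clean_spectrum


class TestBaseline:
    def test_green_peak_exceeds_red_valley(self):
        wl = np.array([550.0, 660.0])
        b = baseline_leaf_spectrum(wl)
        assert b[0] > b[1]

    def test_nir_plateau_exceeds_blue_floor(self):
        wl = np.array([450.0, 900.0])
        b = baseline_leaf_spectrum(wl)
        assert b[1] > b[0]

    def test_water_dip_at_1450(self):
        wl = np.array([1300.0, 1450.0, 1650.0])
        b = baseline_leaf_spectrum(wl)
        assert b[1] < b[0] and b[1] < b[2]

    def test_bounded_in_unit_interval_across_full_span(self):
        wl = np.linspace(423, 1684, 2000)
        b = baseline_leaf_spectrum(wl)
        assert np.all(b > 0) and np.all(b < 1)


class TestGenerateSpectra:
    def test_zero_noise_protein_invertible_at_centres(self):
        cfg = SyntheticConfig(camera="SWIR", n_samples=12, n_bands=80,
                              gain_sd=0.0, offset_sd=0.0, noise_sd=0.0, seed=9)
        sm, truth = generate_spectra(cfg)
        wl = sm.wavelengths
        j = truth.informative_band_indices[0]
        base = baseline_leaf_spectrum(wl)[j]
        # reflectance at the centre band = base*(1 - beta*p*A_j): invert for p
        from leafspec.synthetic import _absorption_profile

        A_j = _absorption_profile(wl, truth.informative_centres_nm, cfg.absorption_width)[j]
        p_rec = (1.0 - sm.values[:, j] / base) / (cfg.beta * A_j)
        np.testing.assert_allclose(p_rec, truth.protein_per_sample, rtol=1e-10)

    def test_reflectance_decreases_with_protein_at_centres(self):
        cfg = SyntheticConfig(camera="SWIR", n_samples=30, n_bands=80,
                              gain_sd=0.0, offset_sd=0.0, noise_sd=0.0, seed=2)
        sm, truth = generate_spectra(cfg)
        order = np.argsort(truth.protein_per_sample)
        for j in truth.informative_band_indices:
            vals = sm.values[order, j]
            assert np.all(np.diff(vals) < 0)

    def test_protein_tertile_means_ordered_under_default_noise(self, default_swir):
        sm, truth = default_swir
        p = truth.protein_per_sample
        tert = np.digitize(p, np.quantile(p, [1 / 3, 2 / 3]))
        for j in truth.informative_band_indices:
            means = [sm.values[tert == k, j].mean() for k in range(3)]
            assert means[0] > means[1] > means[2]

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(camera="VNIR", n_samples=8, n_bands=30, seed=77)
        a, ta = generate_spectra(cfg)
        b, tb = generate_spectra(cfg)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(ta.protein_per_sample, tb.protein_per_sample)

    def test_two_camera_matrices_share_protein(self):
        cfg = SyntheticConfig(camera="BOTH", n_samples=10, n_bands=40, seed=5)
        vnir, swir, truth = generate_two_camera_spectra(cfg)
        assert vnir.n_samples == swir.n_samples == 10
        assert vnir.wavelengths[0] == 423.0 and swir.wavelengths[-1] == 1684.0
        assert truth.protein_per_sample.shape == (10,)

    def test_negative_reflectance_config_rejected(self):
        cfg = SyntheticConfig(camera="SWIR", n_samples=5, n_bands=30,
                              beta=0.05, protein_range=(10.0, 46.0), seed=0)
        with pytest.raises(ConfigError):
            generate_spectra(cfg)

    def test_scatter_correction_removes_gain_offset_variance(self):
        # Replicates at fixed protein: the between-replicate variance of the
        # centre-band value that is attributable to gain/offset (i.e. beyond
        # what band noise alone produces) must drop by >= 90 % after SNV and
        # after MSC.  Variances are normalized by the across-band variance of
        # the mean spectrum because SNV output lives on its own scale.
        cfg = SyntheticConfig(camera="SWIR", n_samples=2, n_bands=80, seed=0)
        wl = camera_grid("SWIR", 80)
        clean = clean_spectrum(wl, 25.0, cfg, "SWIR")
        rng = np.random.default_rng(3)
        reps = np.repeat(clean, 400, axis=0)
        gain = rng.normal(1.0, cfg.gain_sd, size=(400, 1))
        offset = rng.normal(0.0, cfg.offset_sd, size=(400, 1))
        noise = rng.normal(0.0, cfg.noise_sd, size=(400, 80))
        full = gain * reps + offset + noise
        noise_only = reps + noise
        j = int(np.argmin(np.abs(wl - 1180.0)))
        from leafspec.preprocessing import SpectraMatrix

        def rel_var(X):
            return X[:, j].var() / X.mean(axis=0).var()

        for transform in (snv, msc):
            before = rel_var(full) - rel_var(noise_only)
            after = rel_var(transform(SpectraMatrix(full, wl))[0].values) - rel_var(
                transform(SpectraMatrix(noise_only, wl))[0].values
            )
            assert after <= 0.1 * before


class TestLeafCube:
    def test_calibration_inverts_the_construction(self, small_cube):
        raw, white, dark, truth = small_cube
        cal = calibrate(raw, white, dark)
        np.testing.assert_allclose(
            cal.data, truth.extras["reflectance"], atol=1e-12
        )

    def test_vein_truth_below_mesophyll_truth(self, small_cube):
        *_, truth = small_cube
        pmap = truth.protein_map
        vein = truth.vein_mask & truth.true_mask
        meso = truth.true_mask & ~truth.vein_mask
        assert np.nanmedian(pmap[vein]) < np.nanmedian(pmap[meso])

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(camera="SWIR", n_bands=20, image_size=(20, 24), seed=8)
        a = generate_leaf_cube(cfg)
        b = generate_leaf_cube(cfg)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[3].protein_map, b[3].protein_map)

    def test_both_cameras_rejected_for_cubes(self):
        with pytest.raises(ConfigError):
            generate_leaf_cube(SyntheticConfig(camera="BOTH"))


class TestReferences:
    def _truth(self, n, seed=0):
        cfg = SyntheticConfig(camera="SWIR", n_samples=n, n_bands=20, seed=seed)
        return generate_spectra(cfg)[1]

    def test_zero_noise_recovers_truth_exactly(self):
        truth = self._truth(25)
        refs = generate_references(truth, assay_noise_sd=0.0, seed=1)
        np.testing.assert_allclose(
            refs["protein_g_per_100g"].to_numpy(), truth.protein_per_sample,
            atol=1e-10,
        )

    def test_noise_sd_matches_requested_scale(self):
        truth = self._truth(1000, seed=3)
        refs = generate_references(truth, assay_noise_sd=0.3, seed=4)
        err = refs["protein_g_per_100g"].to_numpy() - truth.protein_per_sample
        assert err.std() == pytest.approx(0.3, rel=0.15)

    def test_titration_volumes_valid_and_consistent(self):
        truth = self._truth(50, seed=6)
        refs = generate_references(truth, assay_noise_sd=0.5, seed=7)
        assert (refs["V1"] >= refs["V2"]).all()
        recomputed = [
            kjeldahl_protein(KjeldahlAssay(V1=r.V1, V2=r.V2, V3=r.V3, C=r.C,
                                           m=r.m, F=r.F))
            for r in refs.itertuples()
        ]
        np.testing.assert_allclose(recomputed, refs["protein_g_per_100g"], atol=1e-12)
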