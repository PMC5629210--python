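"""Line-scan junction quantification: projections, profiles, measures."""

import numpy as np
import pandas as pd
import pytest

from zamech import junction as jq, synthetic as syn
from zamech.errors import FitError, ValidationError


def flat_profile(value=100.0, n=201, px=0.1):
    x = (np.arange(n) - n // 2) * px
    return jq.JunctionProfile(positions_um=x, intensities=np.full(n, value),
                              pixel_size_um=px)


def gaussian_profile(amp=500.0, sigma_um=0.8, baseline=100.0, n=41, px=0.5,
                     center=0.0):
    x = (np.arange(n) - n // 2) * px
    y = amp * np.exp(-((x - center) ** 2) / (2 * sigma_um ** 2)) + baseline
    return jq.JunctionProfile(positions_um=x, intensities=y, pixel_size_um=px)


@pytest.fixture(scope="module")
def clean_image():
    return syn.gen_junction_image(
        syn.JunctionImageSpec(poisson_noise=False, read_noise_sd=0.0))


class TestProjection:
    def test_identical_planes(self):
        plane = np.full((8, 8), 7.0)
        stack = jq.CalibratedImage(np.stack([plane] * 4), 0.1, z_spacing_um=0.19)
        out = jq.max_project_apical(stack)
        np.testing.assert_allclose(out.data, plane)

    def test_pixelwise_maximum(self):
        stack = jq.CalibratedImage(
            np.array([[[1.0]], [[5.0]], [[3.0]]]), 0.1)
        assert jq.max_project_apical(stack).data[0, 0] == 5.0

    def test_apical_brightest_plane_dominates(self):
        """Projection peak equals the brightest plane's amplitude."""
        img, roi, _ = syn.gen_junction_image(syn.JunctionImageSpec(
            n_planes=3, plane_scales=(0.5, 1.0, 0.3),
            poisson_noise=False, read_noise_sd=0.0))
        proj = jq.max_project_apical(img)
        m = jq.gaussian_peak(jq.extract_line_scan(proj, roi))
        assert m.value == pytest.approx(500.0, rel=1e-6)

    def test_too_few_planes_rejected(self):
        stack = jq.CalibratedImage(np.zeros((2, 4, 4)), 0.1)
        with pytest.raises(ValidationError):
            jq.max_project_apical(stack, n_sections=3)


class TestLineScan:
    def test_uniform_image_gives_flat_profile(self):
        img = jq.CalibratedImage(np.full((100, 100), 42.0), 0.2)
        roi = jq.JunctionRoi(np.array([[50.0, 20.0], [50.0, 80.0]]))
        prof = jq.extract_line_scan(img, roi, length_um=10, width_px=10)
        np.testing.assert_allclose(prof.intensities, 42.0)

    def test_profile_center_finds_junction(self, clean_image):
        img, roi, truth = clean_image
        prof = jq.extract_line_scan(img, roi)
        m = jq.gaussian_peak(prof)
        # junction runs through the ROI center: peak within 1 px of 0
        assert abs(m.params["center_um"]) <= img.pixel_size_um

    def test_rotation_equivariance(self):
        """Rotating the scene with its ROI changes the peak by <= 2%."""
        ref_spec = syn.JunctionImageSpec(poisson_noise=False, read_noise_sd=0.0)
        img0, roi0, _ = syn.gen_junction_image(ref_spec)
        m0 = jq.gaussian_peak(jq.extract_line_scan(img0, roi0))
        imgr, roir, _ = syn.gen_junction_image(
            syn.JunctionImageSpec(junction_angle_deg=53.0,
                                  poisson_noise=False, read_noise_sd=0.0))
        mr = jq.gaussian_peak(jq.extract_line_scan(imgr, roir))
        assert mr.value == pytest.approx(m0.value, rel=0.02)

    def test_scan_exiting_bounds_rejected(self):
        img = jq.CalibratedImage(np.zeros((50, 50)), 0.1)
        roi = jq.JunctionRoi(np.array([[2.0, 2.0], [2.0, 10.0]]))
        with pytest.raises(ValidationError, match="bounds"):
            jq.extract_line_scan(img, roi, length_um=20)

    def test_zero_length_roi_rejected(self):
        img = jq.CalibratedImage(np.zeros((50, 50)), 0.1)
        roi = jq.JunctionRoi(np.array([[25.0, 25.0], [25.0, 25.0]]))
        with pytest.raises(ValidationError):
            jq.extract_line_scan(img, roi, length_um=2)


class TestGaussianPeak:
    def test_exact_profile(self):
        m = jq.gaussian_peak(gaussian_profile())
        assert m.value == pytest.approx(500.0, rel=1e-6)
        assert m.background == pytest.approx(100.0, rel=1e-2)
        assert m.params["baseline"] == pytest.approx(100.0, rel=1e-4)

    def test_flat_profile_flagged(self):
        m = jq.gaussian_peak(flat_profile())
        assert m.value == 0.0
        assert "no-peak" in m.flags

    def test_linearity_in_intensity(self):
        m1 = jq.gaussian_peak(gaussian_profile(amp=200.0))
        m3 = jq.gaussian_peak(gaussian_profile(amp=600.0))
        assert m3.value == pytest.approx(3 * m1.value, rel=1e-6)

    def test_constant_offset_removed(self):
        """Adding a constant offset leaves the amplitude unchanged."""
        m0 = jq.gaussian_peak(gaussian_profile(baseline=0.0))
        mb = jq.gaussian_peak(gaussian_profile(baseline=250.0))
        assert mb.value == pytest.approx(m0.value, rel=1e-6)

    def test_noisy_amplitude_recovery(self):
        """Median amplitude error under Poisson noise stays below 5%."""
        errs = []
        for i, amp in enumerate([200.0, 500.0, 1000.0]):
            for rep in range(5):
                img, roi, truth = syn.gen_junction_image(syn.JunctionImageSpec(
                    seed=10 * i + rep, band_amplitude=amp))
                m = jq.gaussian_peak(jq.extract_line_scan(img, roi))
                errs.append(abs(m.value / amp - 1))
        assert np.median(errs) < 0.05


class TestBandAuc:
    def test_rectangular_band(self):
        """Rectangular band of height h and width 21 px, zero background."""
        n, h = 201, 40.0
        y = np.zeros(n)
        y[90:111] = h
        prof = jq.JunctionProfile(positions_um=(np.arange(n) - 100) * 0.1,
                                  intensities=y, pixel_size_um=0.1)
        m = jq.band_auc(prof, centers_idx=[100])
        assert m.value == pytest.approx(21 * h)
        assert m.background == 0.0

    def test_all_background_profile(self):
        m = jq.band_auc(flat_profile(80.0), centers_idx=[100])
        assert m.value == pytest.approx(0.0, abs=1e-9)

    def test_two_band_mass_recovery(self):
        img, roi, truth = syn.gen_junction_image(syn.JunctionImageSpec(
            two_band=True, poisson_noise=False, read_noise_sd=0.0))
        prof = jq.extract_line_scan(img, roi)
        m = jq.band_auc(prof)
        assert len(m.params["centers_idx"]) == 2
        assert m.value == pytest.approx(truth["band_mass"], rel=0.05)
        centers = np.sort(m.params["centers_um"])
        np.testing.assert_allclose(centers, [-1.0, 1.0], atol=0.11)

    def test_constant_offset_removed(self):
        img, roi, truth = syn.gen_junction_image(syn.JunctionImageSpec(
            two_band=True, background=300.0, poisson_noise=False, read_noise_sd=0.0))
        m = jq.band_auc(jq.extract_line_scan(img, roi))
        assert m.value == pytest.approx(truth["band_mass"], rel=0.05)


class TestColoc:
    def test_identical_profiles_ratio_one(self):
        p = gaussian_profile()
        m = jq.coloc_at_reference_peak(p, p)
        assert m.params["ratio"] == pytest.approx(1.0, rel=1e-3)

    def test_zero_target(self):
        ref = gaussian_profile()
        zero = jq.JunctionProfile(positions_um=ref.positions_um,
                                  intensities=np.zeros_like(ref.intensities),
                                  pixel_size_um=ref.pixel_size_um)
        m = jq.coloc_at_reference_peak(zero, ref)
        assert m.value == pytest.approx(0.0, abs=1e-9)
        assert m.params["ratio"] == pytest.approx(0.0, abs=1e-9)

    def test_generator_ratio_recovery(self):
        img, roi, truth = syn.gen_junction_image(syn.JunctionImageSpec(
            seed=4, coloc_ratio=0.4))
        ref_prof = jq.extract_line_scan(img, roi)
        tgt_prof = jq.extract_line_scan(truth["coloc_image"], roi)
        m = jq.coloc_at_reference_peak(tgt_prof, ref_prof)
        assert m.params["ratio"] == pytest.approx(0.4, rel=0.05)

    def test_flat_reference_rejected(self):
        with pytest.raises(FitError):
            jq.coloc_at_reference_peak(gaussian_profile(), gaussian_profile(amp=0.0))


class TestJunctionCytoplasmRatio:
    def test_uniform_image_ratio_one(self):
        img = jq.CalibratedImage(np.full((101, 101), 90.0), 0.1)
        roi = jq.JunctionRoi(np.array([[50.0, 10.0], [50.0, 90.0]]))
        cyto = np.zeros((101, 101), dtype=bool)
        cyto[:, 75:95] = True
        m = jq.junction_cytoplasm_ratio(img, roi, cyto)
        assert m.value == pytest.approx(1.0)

    def test_exact_masks(self):
        img, roi, cyto, truth = syn.gen_ahph_image(syn.AhphImageSpec(
            enrichment=3.0, poisson_noise=False, read_noise_sd=0.0))
        m = jq.junction_cytoplasm_ratio(img, roi, cyto)
        assert m.value == pytest.approx(3.0, rel=1e-9)

    def test_noisy_enrichment_recovery(self):
        img, roi, cyto, truth = syn.gen_ahph_image(syn.AhphImageSpec(seed=9,
                                                                     enrichment=2.2))
        m = jq.junction_cytoplasm_ratio(img, roi, cyto)
        assert m.value == pytest.approx(2.2, rel=0.05)

    def test_scale_invariance(self):
        img, roi, cyto, _ = syn.gen_ahph_image(syn.AhphImageSpec(
            poisson_noise=False, read_noise_sd=0.0))
        scaled = jq.CalibratedImage(img.data * 7.0, img.pixel_size_um)
        m1 = jq.junction_cytoplasm_ratio(img, roi, cyto)
        m2 = jq.junction_cytoplasm_ratio(scaled, roi, cyto)
        assert m2.value == pytest.approx(m1.value, rel=1e-12)

    def test_empty_mask_rejected(self):
        img = jq.CalibratedImage(np.full((50, 50), 10.0), 0.1)
        roi = jq.JunctionRoi(np.array([[25.0, 5.0], [25.0, 45.0]]))
        with pytest.raises(ValidationError, match="empty"):
            jq.junction_cytoplasm_ratio(img, roi, np.zeros((50, 50), dtype=bool))

    def test_overlapping_mask_rejected(self):
        img = jq.CalibratedImage(np.full((50, 50), 10.0), 0.1)
        roi = jq.JunctionRoi(np.array([[25.0, 5.0], [25.0, 45.0]]))
        cyto = np.ones((50, 50), dtype=bool)
        with pytest.raises(ValidationError, match="overlap"):
            jq.junction_cytoplasm_ratio(img, roi, cyto)


class TestBatch:
    def _table(self, n, cond="KD"):
        return pd.DataFrame({"condition": [cond] * n, "experiment": "e1",
                             "value": np.linspace(1, 2, n)})

    def test_minimum_sampling_guard(self):
        with pytest.raises(ValidationError, match="25"):
            jq.summarize_measurements(self._table(10), readout="IF")
        with pytest.raises(ValidationError, match="60"):
            jq.summarize_measurements(self._table(40), readout="AHPH")
        # sufficient counts and force both succeed
        assert len(jq.summarize_measurements(self._table(30), readout="IF")) == 1
        assert len(jq.summarize_measurements(self._table(10), readout="IF",
                                             force=True)) == 1

    def test_normalize_to_control(self):
        df = pd.concat([self._table(30, "control"), self._table(30, "KD")])
        df.loc[df["condition"] == "KD", "value"] *= 0.5
        out = jq.normalize_measurements(df, "control")
        ctrl_mean = out[out["condition"] == "control"]["value_norm"].mean()
        assert ctrl_mean == pytest.approx(1.0)
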