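"""Projection, PSF, detection-weight and planar-simulation contracts."""

import logging
import math
from dataclasses import replace

import numpy as np
import pytest

import hmrcal as h
from hmrcal.collimator import EmissionLine, attenuation_table
from hmrcal.phantom import DigitalPhantom
from hmrcal.projector import (
    DEFAULT_CONSTANTS,
    ModelConstants,
    expected_image,
    ideal_projection,
)

LEHR = h.CollimatorSpec(1.5, 0.2, 35.0, label="LEHR")
MEGP = h.CollimatorSpec(3.0, 1.05, 58.0, label="MEGP")
DET = h.STANDARD_DETECTOR


def toy_phantom(shape=(32, 32), thicknesses=(10.0, 10.0, 30.0), density=1.19):
    layers = np.zeros((3, *shape))
    dmap = np.full(shape, density)
    masks = {"background": np.ones(shape, dtype=bool)}
    return DigitalPhantom(
        grid_shape=shape,
        pixel_size=2.21,
        layer_thicknesses=thicknesses,
        activity_layers=layers,
        density_map=dmap,
        compartment_masks=masks,
    )


class TestAttenuationProjection:
    def test_zero_activity_gives_zero_image(self):
        ph = toy_phantom()
        assert np.all(h.attenuation_projection(ph, 159.0, "anterior") == 0.0)

    def test_zero_attenuation_gives_plain_layer_sum(self):
        ph = toy_phantom(density=0.0)
        ph.activity_layers[0][:] = 1.0
        ph.activity_layers[1][:] = 2.0
        ph.activity_layers[2][:] = 3.0
        for view in ("anterior", "posterior"):
            assert np.allclose(h.attenuation_projection(ph, 159.0, view), 6.0)

    def test_single_pixel_attenuated_by_overlying_depth(self):
        ph = toy_phantom()
        ph.activity_layers[1][10, 7] = 1.0  # layer-1 centre at depth 15 mm
        proj = h.attenuation_projection(ph, 159.0, "anterior")
        mu = attenuation_table.mass_mu("pmma", 159.0) / 10.0 * 1.19
        assert proj[10, 7] == pytest.approx(math.exp(-mu * 15.0))
        assert np.count_nonzero(proj) == 1

    def test_posterior_view_reverses_depth_and_mirrors(self):
        ph = toy_phantom()
        ph.activity_layers[1][10, 7] = 1.0
        proj = h.attenuation_projection(ph, 159.0, "posterior")
        mu = attenuation_table.mass_mu("pmma", 159.0) / 10.0 * 1.19
        # path from layer-1 centre to the posterior face is 50 - 15 = 35 mm
        assert proj[10, 31 - 7] == pytest.approx(math.exp(-mu * 35.0))
        assert proj[10, 7] == 0.0

    def test_unknown_view_rejected(self):
        with pytest.raises(ValueError):
            h.attenuation_projection(toy_phantom(), 159.0, "lateral")


class TestSystemPsf:
    def test_normalized_and_rotation_symmetric(self):
        k = h.system_psf(LEHR, DET, 159.0, 50.0)
        assert k.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(k, np.rot90(k))

    def test_no_penetration_gives_pure_gaussian(self):
        consts = ModelConstants(penetration_axial=0.0, penetration_broad=0.0)
        k = h.system_psf(LEHR, DET, 159.0, 50.0, consts=consts)
        # a pure Gaussian has no heavy tail: radial log is quadratic
        fwhm = math.hypot(h.geometric_fwhm(LEHR, 159.0, 50.0), DET.intrinsic_resolution)
        sigma_px = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / 2.21
        center = k.shape[0] // 2
        profile = k[center, center:center + 8]
        expected = profile[0] * np.exp(-0.5 * (np.arange(8) / sigma_px) ** 2)
        assert np.allclose(profile, expected, rtol=1e-6)

    def test_megp_photopeak_tail_weight_negligible(self):
        from hmrcal.projector import _psf_weights

        sharp, tail = _psf_weights(MEGP, 159.0, DEFAULT_CONSTANTS)
        assert tail / (sharp + tail) < 1e-3


class TestDetectionWeight:
    def test_vanishing_window_kills_all_lines(self):
        acq = h.AcquisitionSpec(window_halfwidth=1e-6)
        for line in h.emission_spectrum():
            assert h.detection_weight(DET, line, acq) < 1e-4

    def test_photopeak_weight_exceeds_half(self, acq):
        assert h.detection_weight(DET, EmissionLine(159.0, 0.833), acq) > 0.5

    def test_thicker_crystal_detects_more_photopeak(self, acq):
        thick = replace(DET, crystal_thickness=15.9)
        line = EmissionLine(159.0, 0.833)
        assert h.detection_weight(thick, line, acq) > h.detection_weight(DET, line, acq)

    def test_high_energy_weight_is_small_but_positive(self, acq):
        w = h.detection_weight(DET, EmissionLine(529.0, 0.0139), acq)
        assert 0.0 < w < 0.5


class TestSimulatePlanar:
    def test_same_seed_bitwise_identical(self, calibrated, acq, cache):
        a = h.simulate_planar(calibrated, LEHR, DET, acq, "anterior", cache=cache)
        b = h.simulate_planar(calibrated, LEHR, DET, acq, "anterior", cache=cache)
        assert np.array_equal(a.counts, b.counts)

    def test_doubling_budget_doubles_counts(self, calibrated, cache):
        acq1 = h.AcquisitionSpec(total_photons=1e6, seed=3)
        acq2 = h.AcquisitionSpec(total_photons=2e6, seed=3)
        t1 = h.simulate_planar(calibrated, LEHR, DET, acq1, "anterior", cache=cache).counts.sum()
        t2 = h.simulate_planar(calibrated, LEHR, DET, acq2, "anterior", cache=cache).counts.sum()
        assert t2 / t1 == pytest.approx(2.0, rel=0.01)

    def test_noise_free_expectation_is_deterministic(self, calibrated, acq, cache):
        a = expected_image(calibrated, MEGP, DET, acq, "anterior", cache=cache)
        b = expected_image(calibrated, MEGP, DET, acq, "anterior", cache=cache)
        assert np.array_equal(a, b)

    def test_megp_preserves_contrast_better_than_lehr(self, calibrated, acq, cache, rois):
        """Septal penetration lowers the anterior HMR more for the
        low-energy than the medium-energy collimator."""
        hmr = {}
        for spec in (LEHR, MEGP):
            img = h.simulate_planar(
                calibrated, spec, DET, acq, "anterior", noise=False, cache=cache
            )
            hmr[spec.label] = h.compute_hmr(img, rois)
        assert abs(hmr["MEGP"] - 2.6) < abs(hmr["LEHR"] - 2.6)
        assert hmr["LEHR"] < hmr["MEGP"] <= 2.65

    def test_low_budget_logs_warning(self, calibrated, cache, caplog):
        tiny = h.AcquisitionSpec(total_photons=300.0, seed=0)
        with caplog.at_level(logging.WARNING, logger="hmrcal"):
            h.simulate_planar(calibrated, LEHR, DET, tiny, "anterior", cache=cache)
        assert any("heart ROI expectation" in r.message for r in caplog.records)

    def test_detector_resolution_robustness(self, calibrated, cache, acq):
        """Varying intrinsic resolution 3.3-4.5 mm and energy resolution
        9.5-9.9% moves the coefficient by far less than 0.03."""
        base = h.simulate_record(
            calibrated, MEGP, DET, acq, n_replicates=1, noise=False, cache=cache
        ).compensated_coefficient
        for det in (
            replace(DET, intrinsic_resolution=3.3),
            replace(DET, intrinsic_resolution=4.5),
            replace(DET, energy_resolution_140=0.095),
            replace(DET, energy_resolution_140=0.099),
        ):
            cc = h.simulate_record(
                calibrated, MEGP, det, acq, n_replicates=1, noise=False, cache=cache
            ).compensated_coefficient
            assert abs(cc - base) < 0.03


def test_image_round_trip(tmp_path, calibrated, acq, cache):
    img = h.simulate_planar(calibrated, LEHR, DET, acq, "posterior", cache=cache)
    from hmrcal.projector import load_image, save_image

    save_image(img, tmp_path / "img")
    loaded = load_image(tmp_path / "img")
    assert np.array_equal(loaded.counts, img.counts)
    assert loaded.view == "posterior"
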