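"""Collimator design quantities against hand and table-lookup oracles."""

import math

import numpy as np
import pandas as pd
import pytest

import hmrcal as h
from hmrcal.collimator import CollimatorError

LEHR = h.CollimatorSpec(1.5, 0.2, 35.0, label="LEHR")
MEGP = h.CollimatorSpec(3.0, 1.05, 58.0, label="MEGP")


def mu_pb_oracle(energy):
    """Independent log-log table lookup straight from the bundled CSV."""
    from importlib import resources

    with resources.files("hmrcal.data").joinpath("attenuation.csv").open() as fh:
        frame = pd.read_csv(fh, comment="#")
    return (
        math.exp(
            np.interp(
                math.log(energy),
                np.log(frame["energy_kev"]),
                np.log(frame["pb"]),
            )
        )
        * 11.34
        / 10.0
    )


class TestSpec:
    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(CollimatorError):
            h.CollimatorSpec(0.0, 0.2, 35.0)
        with pytest.raises(CollimatorError):
            h.CollimatorSpec(1.5, -0.2, 35.0)

    def test_rejects_non_lead_density(self):
        with pytest.raises(CollimatorError):
            h.CollimatorSpec(1.5, 0.2, 35.0, material_density=5.0)


class TestEffectiveLength:
    def test_opaque_limit_approaches_physical_length(self):
        # at the most attenuated energy in the table, 2/mu is sub-mm
        assert h.effective_length(LEHR, 100.0) == pytest.approx(35.0, abs=0.5)

    def test_megp_at_photopeak(self):
        value = h.effective_length(MEGP, 159.0)
        assert 57.0 < value < 58.0

    def test_additivity_in_length(self):
        longer = h.CollimatorSpec(3.0, 1.05, 68.0)
        assert h.effective_length(longer, 159.0) - h.effective_length(MEGP, 159.0) == pytest.approx(10.0)

    def test_transparent_collimator_raises(self):
        thin = h.CollimatorSpec(1.5, 0.2, 10.0)
        with pytest.raises(CollimatorError):
            h.effective_length(thin, 600.0)


class TestGeometricFwhm:
    def test_source_at_face_is_near_hole_diameter(self):
        value = h.geometric_fwhm(LEHR, 159.0, 0.0)
        assert LEHR.hole_diameter <= value < 1.05 * LEHR.hole_diameter

    def test_direct_formula_arithmetic(self):
        # d = 3.0 mm, L_eff in (57, 58) mm, b = 100 mm -> ~8.2 mm
        value = h.geometric_fwhm(MEGP, 159.0, 100.0)
        assert 8.1 < value < 8.3

    def test_linear_in_hole_diameter(self):
        doubled = h.CollimatorSpec(3.0, 1.05, 35.0)
        single = h.CollimatorSpec(1.5, 1.05, 35.0)
        assert h.geometric_fwhm(doubled, 159.0, 80.0) == pytest.approx(
            2.0 * h.geometric_fwhm(single, 159.0, 80.0)
        )

    def test_negative_distance_raises(self):
        with pytest.raises(CollimatorError):
            h.geometric_fwhm(LEHR, 159.0, -1.0)


class TestMinimalSeptalPath:
    @pytest.mark.parametrize(
        "spec, expected",
        [(LEHR, 2.1875), (MEGP, 58.0 * 1.05 / 7.05)],
        ids=["lehr", "megp"],
    )
    def test_hand_arithmetic(self, spec, expected):
        assert h.minimal_septal_path(spec) == pytest.approx(expected)

    def test_vanishing_septa(self):
        thin = h.CollimatorSpec(1.5, 1e-9, 35.0)
        assert h.minimal_septal_path(thin) < 1e-7


class TestPenetrationFraction:
    def test_transparent_limit(self):
        thin = h.CollimatorSpec(1.5, 1e-6, 35.0)
        assert h.penetration_fraction(thin, 159.0) == pytest.approx(1.0, abs=1e-4)

    def test_lehr_photopeak_below_one_percent(self):
        assert h.penetration_fraction(LEHR, 159.0) < 0.01

    @pytest.mark.parametrize("energy", [159.0, 529.0])
    def test_matches_table_lookup_exponential_oracle(self, energy):
        expected = math.exp(-mu_pb_oracle(energy) * 2.1875)
        assert h.penetration_fraction(LEHR, energy) == pytest.approx(expected, rel=1e-9)

    def test_lehr_high_energy_exceeds_03(self):
        assert h.penetration_fraction(LEHR, 529.0) > 0.3

    def test_energy_out_of_table_raises(self):
        with pytest.raises(CollimatorError):
            h.penetration_fraction(LEHR, 50.0)

    def test_grid_monotonicity_at_529(self):
        """Exhaustive over the design grid: penetration non-increasing in t
        and L, non-decreasing in d, at the dominant high-energy line."""
        from hmrcal.pipeline import SIM2_DIAMETERS, SIM2_LENGTHS, SIM2_SEPTA

        pen = {
            (d, t, L): h.penetration_fraction(h.CollimatorSpec(d, t, L), 529.0)
            for d in SIM2_DIAMETERS
            for t in SIM2_SEPTA
            for L in SIM2_LENGTHS
        }
        for d in SIM2_DIAMETERS:
            for L in SIM2_LENGTHS:
                vals = [pen[(d, t, L)] for t in SIM2_SEPTA]
                assert all(a >= b for a, b in zip(vals, vals[1:]))
        for d in SIM2_DIAMETERS:
            for t in SIM2_SEPTA:
                vals = [pen[(d, t, L)] for L in SIM2_LENGTHS]
                assert all(a >= b for a, b in zip(vals, vals[1:]))
        for t in SIM2_SEPTA:
            for L in SIM2_LENGTHS:
                vals = [pen[(d, t, L)] for d in SIM2_DIAMETERS]
                assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_low_energy_penetrates_more_than_medium_energy_per_camera(self):
        presets = h.load_collimator_presets()
        for camera, group in presets.groupby("camera"):
            le = group[group["energy_class"] != "me"]
            me = group[group["energy_class"] == "me"]
            if le.empty or me.empty:
                continue
            p = lambda r: h.penetration_fraction(
                h.CollimatorSpec(r.hole_diameter_mm, r.septum_mm, r.length_mm), 529.0
            )
            assert min(p(r) for r in le.itertuples()) > max(p(r) for r in me.itertuples())


class TestEmissionSpectrum:
    def test_exactly_one_line_in_photopeak_window(self):
        lines = [l for l in h.emission_spectrum() if 143.1 <= l.energy <= 174.9]
        assert len(lines) == 1 and lines[0].energy == 159.0

    def test_principal_line_dominates(self):
        spectrum = h.emission_spectrum()
        assert spectrum[0].abundance > 0.8

    def test_high_energy_abundance_sum(self):
        total = sum(l.abundance for l in h.emission_spectrum() if l.energy > 400.0)
        assert total == pytest.approx(0.025, abs=0.01)

    def test_sorted_with_valid_abundances(self):
        spectrum = h.emission_spectrum()
        energies = [l.energy for l in spectrum]
        assert energies == sorted(energies)
        assert all(0.0 < l.abundance <= 1.0 for l in spectrum)


class TestAttenuationTable:
    def test_rejects_non_decreasing_coefficients(self):
        bad = pd.DataFrame(
            {"energy_kev": [100, 200], "pb": [1.0, 2.0], "nai": [1.0, 0.5], "pmma": [0.2, 0.1]}
        )
        with pytest.raises(ValueError):
            h.AttenuationTable(bad)

    def test_interpolation_recovers_knots(self):
        assert h.attenuation_table.mass_mu("pb", 159.0) == pytest.approx(1.910)


def test_table1_presets_load_as_specs():
    presets = h.load_collimator_presets()
    assert len(presets) == 21  # 18 published systems + the Discovery trio
    spec = h.get_collimator_preset("GE Infinia", "LEHR")
    assert spec.as_features() == (1.5, 0.2, 35.0)
    with pytest.raises(KeyError):
        h.get_collimator_preset("GE Infinia", "nope")
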