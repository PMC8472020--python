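"""Synthetic-scene generator: endmember shape, determinism, ground truth."""

import numpy as np
import pytest

import hsimeat as h
from hsimeat import segmentation, synthcube
from hsimeat.errors import ConfigError, GeometryError, InvalidGridError


@pytest.fixture
def flat_profile():
    return h.SpeciesProfile(
        species="mutton",
        state="raw",
        baseline_knots=((380.6, 0.2), (700.0, 0.5), (1012.2, 0.4)),
        dips=(),
    )


class TestMakeEndmember:
    def test_zero_depth_dips_reproduce_baseline(self, flat_profile):
        wl = np.linspace(380.6, 1012.2, 100)
        from scipy.interpolate import PchipInterpolator

        knots = np.asarray(flat_profile.baseline_knots)
        baseline = PchipInterpolator(knots[:, 0], knots[:, 1])(wl)
        with_dips = h.SpeciesProfile(
            "mutton", "raw", flat_profile.baseline_knots,
            dips=((500.0, 10.0, 0.0), (800.0, 20.0, 0.0)),
        )
        np.testing.assert_array_equal(h.make_endmember(with_dips, wl), baseline)

    def test_dip_creates_local_minimum_at_nearest_band(self, flat_profile):
        wl = np.linspace(380.6, 1012.2, 300)
        profile = h.SpeciesProfile(
            "mutton", "raw",
            # near-flat baseline around the dip so it dominates the gradient
            baseline_knots=((380.6, 0.2), (500.0, 0.21), (700.0, 0.5),
                            (1012.2, 0.4)),
            dips=((415.0, 12.0, 0.05),),
        )
        spectrum = h.make_endmember(profile, wl)
        nearest = int(np.argmin(np.abs(wl - 415.0)))
        window = slice(max(nearest - 15, 0), nearest + 15)
        local_min = window.start + int(np.argmin(spectrum[window]))
        assert abs(local_min - nearest) <= 1

    def test_cooked_is_raw_plus_brightness_offset(self, flat_profile):
        wl = np.linspace(380.6, 1012.2, 50)
        raw = h.make_endmember(flat_profile, wl)
        cooked_profile = h.SpeciesProfile(
            "mutton", "cooked", flat_profile.baseline_knots, (),
            brightness_offset=0.08,
        )
        np.testing.assert_allclose(
            h.make_endmember(cooked_profile, wl) - raw, 0.08, atol=1e-15
        )

    def test_nonmonotone_grid_rejected(self, flat_profile):
        with pytest.raises(InvalidGridError):
            h.make_endmember(flat_profile, np.array([400.0, 399.0, 500.0]))

    @pytest.mark.parametrize("species", synthcube.SPECIES)
    @pytest.mark.parametrize("state", ["raw", "cooked"])
    def test_default_profiles_qualitative_shape(self, species, state):
        """Low visible plateau, high NIR plateau, descent toward 1000 nm."""
        wl = h.SynthConfig().wavelengths
        em = h.make_endmember(h.default_profiles(state)[species], wl)
        assert np.all((em >= 0) & (em <= 1))
        low = em[(wl >= 400) & (wl <= 650)].mean()
        high = em[(wl >= 680) & (wl <= 850)].mean()
        assert high > low + 0.1
        assert em[np.argmin(np.abs(wl - 1000))] < em[np.argmin(np.abs(wl - 850))]

    def test_cooked_at_least_raw_everywhere(self):
        wl = h.SynthConfig().wavelengths
        for species in synthcube.SPECIES:
            raw = h.make_endmember(h.default_profiles("raw")[species], wl)
            cooked = h.make_endmember(h.default_profiles("cooked")[species], wl)
            # brighter overall; pigment-dip depths differ slightly at 637 nm
            assert cooked.mean() > raw.mean() + 0.05


class TestRenderSampleCube:
    def test_same_seed_is_bit_identical(self, synth_config, raw_profiles):
        a, _ = h.render_sample_cube(synth_config, raw_profiles["pork"], 7)
        b, _ = h.render_sample_cube(synth_config, raw_profiles["pork"], 7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seed_differs(self, synth_config, raw_profiles):
        a, _ = h.render_sample_cube(synth_config, raw_profiles["pork"], 7)
        b, _ = h.render_sample_cube(synth_config, raw_profiles["pork"], 8)
        assert not np.array_equal(a.data, b.data)

    @pytest.mark.parametrize("species", synthcube.SPECIES)
    def test_band_math_separates_truth_mask_noise_free(self, species):
        config = h.SynthConfig(seed=3, pixel_noise_sd=0.0)
        cube, truth = h.render_sample_cube(
            config, h.default_profiles("raw")[species], 11
        )
        diff = segmentation.band_difference(cube)
        assert np.all(diff[truth] >= 0.15)
        assert np.all(diff[~truth] < 0.15)

    def test_foreground_mean_matches_scaled_endmember(self, raw_profiles):
        config = h.SynthConfig(seed=5)
        profile = raw_profiles["duck"]
        cube, truth = h.render_sample_cube(config, profile, 2)
        fg = cube.data[truth]
        # recover the per-sample factor from one bright band, then check all
        em = h.make_endmember(profile, config.wavelengths)
        factor = fg.mean(axis=0)[200] / em[200]
        tol = 3 * config.pixel_noise_sd / np.sqrt(truth.sum())
        assert np.all(np.abs(fg.mean(axis=0) - em * factor) < tol + 1e-3)

    def test_radius_too_large_raises(self, raw_profiles):
        config = h.SynthConfig(seed=0, image_shape=(32, 32), roll_radius_px=20)
        with pytest.raises(GeometryError):
            h.render_sample_cube(config, raw_profiles["pork"], 0)


class TestReferencePair:
    def test_noise_free_white_is_constant(self, synth_config):
        refs = h.make_reference_pair(synth_config, noise_sd=0.0)
        np.testing.assert_array_equal(refs.white.data, 0.999)
        np.testing.assert_array_equal(refs.dark.data, 0.0)

    def test_calibrating_white_against_itself_is_unity(self, synth_config):
        refs = h.make_reference_pair(synth_config, noise_sd=0.0)
        cal = h.calibrate(refs.white, refs)
        np.testing.assert_allclose(cal.data, 1.0, atol=1e-12)

    def test_calibrating_dark_is_zero(self, synth_config):
        refs = h.make_reference_pair(synth_config, noise_sd=0.0)
        cal = h.calibrate(refs.dark, refs)
        np.testing.assert_allclose(cal.data, 0.0, atol=1e-12)


class TestMakeDataset:
    def test_default_split_counts(self, raw_table):
        assert len(raw_table) == 180
        assert (raw_table.sets == "cal").sum() == 120
        assert (raw_table.sets == "pred").sum() == 60
        for species in synthcube.SPECIES:
            pred = (raw_table.species == species) & (raw_table.sets == "pred")
            assert pred.sum() == 20

    def test_reproducible_under_seed(self, synth_config, raw_profiles):
        a = h.make_dataset(synth_config, raw_profiles.values())
        b = h.make_dataset(synth_config, raw_profiles.values())
        np.testing.assert_array_equal(a.spectra, b.spectra)

    def test_class_means_converge_to_endmember_without_noise(self, raw_profiles):
        config = h.SynthConfig(seed=2, within_class_sd=0.0, pixel_noise_sd=0.0)
        table = h.make_dataset(config, raw_profiles.values())
        for species, profile in raw_profiles.items():
            em = h.make_endmember(profile, config.wavelengths)
            mean = table.spectra[table.species == species].mean(axis=0)
            np.testing.assert_allclose(mean, em, atol=1e-12)

    def test_duplicate_species_rejected(self, synth_config, raw_profiles):
        profiles = [raw_profiles["pork"], raw_profiles["pork"]]
        with pytest.raises(ConfigError):
            h.make_dataset(synth_config, profiles)

    def test_mixed_states_rejected(self, synth_config):
        mix = [h.default_profiles("raw")["pork"],
               h.default_profiles("cooked")["duck"]]
        with pytest.raises(ConfigError):
            h.make_dataset(synth_config, mix)
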