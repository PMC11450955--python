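"""Fat-omics feature blocks: morphology, HU distribution, histograms."""

import numpy as np
import pytest
from scipy import stats as sps

import fatomics as f
from fatomics.extraction import FatWindow, eat_mask_from_sac
from fatomics.features import (
    default_catalog,
    hu_bin_names,
    hu_histogram_features,
    hu_statistics,
    morphology_features,
)
from fatomics.imaging import BinaryMask, ImageVolume
from tests.test_extraction import _ball_mask


def _ellipsoid_mask(semi, spacing=(1.0, 1.0, 1.0), pad=3):
    spacing = np.asarray(spacing, float)
    semi = np.asarray(semi, float)
    n = (np.ceil(2 * semi / spacing) + 2 * pad).astype(int)
    center = (n - 1) / 2.0 * spacing
    zz, yy, xx = np.meshgrid(
        np.arange(n[0]) * spacing[0], np.arange(n[1]) * spacing[1], np.arange(n[2]) * spacing[2],
        indexing="ij",
    )
    d = ((zz - center[0]) / semi[0]) ** 2 + ((yy - center[1]) / semi[1]) ** 2 + (
        (xx - center[2]) / semi[2]
    ) ** 2
    return BinaryMask(d <= 1.0, tuple(spacing))


class TestMorphology:
    def test_unit_cube_volume_conversion(self):
        data = np.zeros((14, 14, 14), dtype=bool)
        data[2:12, 2:12, 2:12] = True
        cube = BinaryMask(data)
        out = morphology_features(cube, cube)
        assert out["EAT_vol"] == pytest.approx(1.0)  # 10x10x10 mm^3 = 1 cm^3
        assert out["SAC_vol"] == pytest.approx(1.0)
        assert out["EAT_sac_fraction"] == pytest.approx(1.0)

    def test_ball_axis_lengths_match_uniform_second_moments(self):
        # eigenvalue of a uniform ball is r^2/5 -> axis = 4r/sqrt(5) = 1.789r
        r = 20.0
        ball = _ball_mask(r)
        out = morphology_features(ball, ball)
        expect = 4.0 * r / np.sqrt(5.0)
        for key in ("Major_axis", "Intermediate_axis", "Minor_axis"):
            assert out[key] == pytest.approx(expect, rel=0.02)
        assert out["Aspect_ratio"] == pytest.approx(1.0, abs=0.03)

    def test_ellipsoid_axis_ordering_and_ratio(self):
        mask = _ellipsoid_mask((20.0, 30.0, 40.0))
        out = morphology_features(mask, mask)
        assert out["Major_axis"] > out["Intermediate_axis"] > out["Minor_axis"]
        assert out["Major_axis"] == pytest.approx(4 * 40 / np.sqrt(5), rel=0.02)
        assert out["Aspect_ratio"] == pytest.approx(2.0, rel=0.03)


class TestHuStatistics:
    def test_symmetric_sample_has_zero_skewness(self):
        vals = np.array([-120.0, -100.0, -80.0, -60.0, -40.0])
        vol = ImageVolume(np.tile(vals, 5).reshape(1, 5, 5).repeat(2, axis=0))
        mask = BinaryMask(np.ones(vol.shape, dtype=bool))
        out = hu_statistics(vol, mask)
        assert out["EAT_HUskewness"] == pytest.approx(0.0, abs=1e-12)
        assert out["Negative_skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_moments(self):
        # {-50,-50,-50,-190}: mean -85; population g1 = -1.1547
        data = np.full((2, 2, 2), 0.0)
        data[0] = [[-50, -50], [-50, -190]]
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0] = True
        out = hu_statistics(ImageVolume(data), BinaryMask(mask))
        assert out["EAT_HUmean"] == pytest.approx(-85.0)
        assert out["EAT_HUskewness"] == pytest.approx(-1.1547, abs=1e-3)
        assert out["Negative_skewness"] == pytest.approx(1.1547, abs=1e-3)
        assert out["EAT_HUmin"] == -190.0 and out["EAT_HUmax"] == -50.0

    def test_gaussian_kurtosis_converges_to_three(self):
        rng = np.random.default_rng(12)
        n = 10**5
        data = rng.normal(-80, 15, size=n).reshape(50, 50, 40)
        out = hu_statistics(ImageVolume(data), BinaryMask(np.ones(data.shape, bool)))
        assert out["EAT_HUkurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_too_few_voxels_rejected(self):
        vol = ImageVolume(np.zeros((2, 2, 2)))
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match=">= 3"):
            hu_statistics(vol, BinaryMask(mask))


class TestHuHistograms:
    def _uniform_volume(self):
        # evenly spread over the window: 8 x 1000 values, 125 per 20-HU bin
        vals = np.linspace(-189.99, -30.01, 8000)
        return ImageVolume(vals.reshape(8, 1000, 1).repeat(2, axis=2)[:, :, :1].reshape(8, 40, 25))

    def test_uniform_distribution_gives_equal_probabilities(self):
        vol = self._uniform_volume()
        mask = BinaryMask(np.ones(vol.shape, bool))
        out = hu_histogram_features(vol, mask, 8)
        for name in hu_bin_names(8, prefix="Pro"):
            assert out[name] == pytest.approx(0.125, abs=1e-3)

    def test_single_bin_mass(self):
        vol = ImageVolume(np.full((3, 4, 4), -40.0))
        mask = BinaryMask(np.ones(vol.shape, bool))
        out = hu_histogram_features(vol, mask, 8)
        assert out["vol_50_30"] == pytest.approx(mask.volume_cm3)
        for name in hu_bin_names(8)[:-1]:
            assert out[name] == 0.0
        assert out["Pro_50_30"] == 1.0

    def test_probabilities_sum_to_one_and_volumes_to_windowed_mass(self, small_phantom):
        vol, sac, _ = small_phantom
        filtered = f.median_filter_slices(vol)
        eat = eat_mask_from_sac(filtered, sac, prefiltered=True)
        for n_bins in (4, 8):
            out = hu_histogram_features(filtered, eat, n_bins)
            probs = [out[n] for n in hu_bin_names(n_bins, prefix="Pro")]
            vols = [out[n] for n in hu_bin_names(n_bins, prefix="vol")]
            assert sum(probs) == pytest.approx(1.0, abs=1e-12)
            assert all(0 <= p <= 1 for p in probs)
            window = FatWindow()
            x = filtered.data[eat.data]
            windowed_cm3 = window.contains(x).sum() * eat.voxel_volume_mm3 / 1000.0
            assert sum(vols) == pytest.approx(windowed_cm3, abs=1e-9)

    def test_skewnormal_phantom_elevated_hu_probability(self):
        # skew-normal HU model tuned so ~37% of windowed fat lies in [-50,-30]
        spec = f.PhantomSpec(
            shape=(26, 64, 64), spacing=(2.5, 2.0, 2.0), semi_axes=(26.0, 50.0, 46.0),
            thickness_kind="constant", t0=14.0, t_amp=0.0,
            hu_dist="skewnorm", hu_shape=-4.0, hu_loc=-38.0, hu_scale=25.0, seed=3,
        )
        vol, sac, truth = f.generate_phantom(spec)
        assert truth["eat_voxels"] >= 10**4
        dist = sps.skewnorm(spec.hu_shape, loc=spec.hu_loc, scale=spec.hu_scale)
        p_window = dist.cdf(-30) - dist.cdf(-190)
        p_bin = (dist.cdf(-30) - dist.cdf(-50)) / p_window
        assert p_bin == pytest.approx(0.37, abs=0.02)  # emulates the elevated-HU case
        eat = eat_mask_from_sac(vol, sac, prefiltered=True)
        out = hu_histogram_features(vol, eat, 8)
        assert out["Pro_50_30"] == pytest.approx(p_bin, abs=0.01)


class TestCatalogAndFullVector:
    def test_catalog_has_148_unique_names_with_published_features(self):
        cat = default_catalog()
        assert len(cat) == 148
        for name in ("EAT_vol", "SAC_vol", "EAT_HUmean", "vol_190_170", "vol_50_30",
                     "Pro_50_30", "Negative_skewness", "Vol_PQ1", "Vol_PQ4",
                     "Thickness_Max", "Thickness_Kurtosis", "Major_axis"):
            assert name in cat.names

    def test_full_vector_length_and_slab_conservation(self, small_phantom_features):
        fv = small_phantom_features
        assert len(fv) == 148
        assert len(set(fv.names)) == 148
        total = sum(fv[f"Vol_PQ{i}"] for i in (1, 2, 3, 4))
        assert total == pytest.approx(fv["EAT_vol"], abs=1e-9)
        shells = sum(fv[f"Vol_Shell{i}"] for i in (1, 2, 3, 4))
        assert shells == pytest.approx(fv["EAT_vol"], abs=1e-9)

    def test_extraction_is_deterministic(self, small_phantom, small_phantom_features):
        vol, sac, _ = small_phantom
        again = f.extract_all(vol, sac)
        np.testing.assert_array_equal(again.values, small_phantom_features.values)

    def test_morphology_independent_of_hu_noise_seed(self, small_phantom):
        vol, sac, truth = small_phantom
        spec2 = f.PhantomSpec(**{**truth["spec"].__dict__, "seed": 99})
        vol2, sac2, _ = f.generate_phantom(spec2)
        np.testing.assert_array_equal(sac.data, sac2.data)
        m1 = morphology_features(sac, truth["eat_mask"])
        m2 = morphology_features(sac2, truth["eat_mask"])
        assert m1 == m2
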