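"""Per-slice filtering chain: noise estimate, NLM, Frangi, binarisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import autoffr as af
from autoffr.filtering import FilterParams, remove_large_components


@pytest.fixture(scope="module")
def textured_slice():
    rng = np.random.default_rng(0)
    base = np.full((96, 96), 60.0)
    base[30:60, 40:50] = 150.0
    return base, rng


class TestNoiseSigma:
    def test_constant_slice_gives_zero(self):
        assert af.estimate_noise_sigma(np.full((32, 32), 7.0)) == 0.0

    def test_recovers_generating_sigma_within_20pct(self, textured_slice):
        base, rng = textured_slice
        noisy = base + rng.normal(0, 10.0, base.shape)
        est = af.estimate_noise_sigma(noisy)
        assert est == pytest.approx(10.0, rel=0.2)

    def test_doubling_noise_doubles_estimate(self, textured_slice):
        base, _ = textured_slice
        rng = np.random.default_rng(42)
        noise = rng.normal(0, 1.0, base.shape)
        e1 = af.estimate_noise_sigma(base + 10 * noise)
        e2 = af.estimate_noise_sigma(base + 20 * noise)
        assert e2 / e1 == pytest.approx(2.0, rel=0.15)


class TestDenoise:
    def test_sigma_zero_is_identity(self, textured_slice):
        base, _ = textured_slice
        out = af.denoise_slice(base, 0.0)
        np.testing.assert_allclose(out, base, atol=1.0)

    def test_reduces_variance_of_pure_noise(self):
        rng = np.random.default_rng(3)
        noisy = np.full((64, 64), 100.0) + rng.normal(0, 10, (64, 64))
        out = af.denoise_slice(noisy, 10.0)
        assert out.var() < noisy.var()

    def test_identical_regions_stay_identical(self):
        # two copies of the same texture average identically away from the
        # seam (the search window sees different neighbourhoods at borders)
        rng = np.random.default_rng(4)
        tile = rng.uniform(50, 200, (32, 32))
        sl = np.hstack([tile, tile])
        out = af.denoise_slice(sl, 5.0)
        np.testing.assert_allclose(out[:, 6:26], out[:, 38:58], atol=1e-6)


class TestVesselness:
    def test_constant_slice_zero_response(self):
        assert af.vesselness_filter(np.full((64, 64), 50.0)).max() == 0.0

    def test_bright_line_scores_far_above_background(self):
        sl = np.full((96, 96), 20.0)
        sl[:, 46:50] = 200.0  # width-4 bright line
        v = af.vesselness_filter(sl)
        line = v[10:-10, 46:50].mean()
        bg = v[10:-10, 5:40].mean()
        assert line > 10 * max(bg, 1e-12)

    def test_disc_interior_below_line_ridge(self):
        sl_line = np.full((96, 96), 20.0)
        sl_line[:, 46:50] = 200.0
        sl_disc = np.full((96, 96), 20.0)
        ii, jj = np.mgrid[:96, :96]
        sl_disc[(ii - 48) ** 2 + (jj - 48) ** 2 <= 30**2] = 200.0
        ridge = af.vesselness_filter(sl_line)[10:-10, 46:50].mean()
        interior = af.vesselness_filter(sl_disc)[(ii - 48) ** 2 + (jj - 48) ** 2 <= 20**2].mean()
        assert interior < ridge


class TestBinarize:
    def test_large_blob_removed_small_kept(self):
        sl = np.zeros((128, 128))
        sl[10:50, 10:35] = 200.0  # 40x25 = 1000 px blob
        sl[80:90, 80:85] = 200.0  # 50 px blob
        out = af.binarize_and_filter(sl, 100, area_threshold=900)
        assert not out[10:50, 10:35].any()
        assert out[80:90, 80:85].all()

    def test_all_dark_slice_empty_mask(self):
        assert not af.binarize_and_filter(np.zeros((32, 32)), 100).any()

    def test_component_of_exactly_900_px_survives(self):
        sl = np.zeros((64, 64))
        sl[2:32, 2:32] = 200.0  # 900 px exactly
        out = af.binarize_and_filter(sl, 100, area_threshold=900)
        assert out.sum() == 900

    def test_threshold_bounds_checked(self):
        with pytest.raises(ValueError):
            af.binarize_and_filter(np.zeros((4, 4)), 300)


@given(t1=st.integers(0, 254))
def test_threshold_monotonicity(t1):
    """Mask at a higher grey threshold is a subset of the lower-threshold mask."""
    rng = np.random.default_rng(7)
    sl = rng.uniform(0, 255, (32, 32))
    t2 = min(t1 + 20, 255)
    m1 = sl > t1
    m2 = sl > t2
    assert not (m2 & ~m1).any()


def test_remove_large_components_empty_input():
    out = remove_large_components(np.zeros((8, 8), dtype=bool), 900)
    assert not out.any()


class TestFilterParams:
    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            FilterParams(grey_thresholds=(140, 125))

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 255\]"):
            FilterParams(grey_thresholds=(100, 300))

    def test_non_positive_parameters_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(nlm_strength=0)


def test_chain_idempotent_on_binarised_phantom():
    """Re-running the chain on an already-binary clean phantom changes nothing."""
    sl = np.zeros((64, 64))
    sl[20:40, 30:36] = 255.0
    fp = FilterParams()
    first = af.binarize_and_filter(af.denoise_slice(sl, af.estimate_noise_sigma(sl)), 125,
                                   fp.area_threshold)
    again = af.binarize_and_filter(
        af.denoise_slice(first * 255.0, af.estimate_noise_sigma(first * 255.0)), 125,
        fp.area_threshold)
    np.testing.assert_array_equal(first, again)
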