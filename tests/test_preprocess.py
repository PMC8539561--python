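import numpy as np
import pytest

import cellmap as cm
from cellmap.preprocess import default_recipe_grid


def lorentzian(x, center, fwhm, amp):
    return amp / (1.0 + ((x - center) / (fwhm / 2.0)) ** 2)


@pytest.fixture
def axis():
    return cm.SpectralAxis(np.arange(400.0, 1801.0))


class TestFitBaseline:
    def test_straight_line_is_own_baseline(self, axis):
        y = 5.0 + 0.01 * axis.values
        base = cm.fit_baseline(cm.Spectrum(axis, y), cm.BaselineRecipe())
        np.testing.assert_allclose(base.intensities, y, rtol=0.01)

    def test_zero_spectrum_zero_baseline(self, axis):
        base = cm.fit_baseline(cm.Spectrum(axis, np.zeros(len(axis))), cm.BaselineRecipe())
        np.testing.assert_allclose(base.intensities, 0.0, atol=1e-9)

    def test_cubic_plus_lorentzian_recovery(self, axis):
        x = axis.values
        t = (x - x.mean()) / 700.0
        background = 100.0 * (1.0 + 0.5 * t + 0.3 * t**2 + 0.2 * t**3)
        peak = lorentzian(x, 1000.0, 12.0, 100.0)
        s = cm.Spectrum(axis, background + peak)
        recovered = cm.subtract_baseline(s, cm.BaselineRecipe())
        k = np.argmin(np.abs(x - 1000.0))
        assert abs(recovered.intensities[k] - 100.0) / 100.0 < 0.05

    def test_polynomial_through_anchors_removes_cubic(self, axis):
        x = axis.values
        t = (x - x.mean()) / 700.0
        background = 50.0 + 10.0 * t - 4.0 * t**3
        peak = lorentzian(x, 900.0, 10.0, 40.0)
        anchors = (420.0, 550.0, 700.0, 1100.0, 1400.0, 1600.0, 1780.0)
        rec = cm.BaselineRecipe(
            method="polynomial-through-anchors", anchors=anchors, degree=3
        )
        resid = cm.subtract_baseline(cm.Spectrum(axis, background + peak), rec)
        k = np.argmin(np.abs(x - 900.0))
        assert abs(resid.intensities[k] - 40.0) / 40.0 < 0.01

    def test_polynomial_degenerate_axis_errors(self):
        axis = cm.SpectralAxis([500.0, 501.0, 502.0])
        rec = cm.BaselineRecipe(
            method="polynomial-through-anchors", anchors=(500.0, 501.0), degree=3
        )
        with pytest.raises(cm.SpectralError):
            cm.fit_baseline(cm.Spectrum(axis, [1.0, 2.0, 3.0]), rec)

    def test_idempotent_on_featureless(self, axis):
        rng = np.random.default_rng(7)
        y = rng.normal(0.0, 1.0, len(axis))
        once = cm.subtract_baseline(cm.Spectrum(axis, y), cm.BaselineRecipe())
        twice = cm.subtract_baseline(once, cm.BaselineRecipe())
        rms = np.sqrt(np.mean(once.intensities**2))
        change = np.sqrt(np.mean((twice.intensities - once.intensities) ** 2))
        assert change < 0.01 * rms or change < 0.05  # < 1% of residual RMS

    def test_peak_height_recovery_many_seeds(self, axis):
        """Median recovered peak-height error across random backgrounds < 5%."""
        x = axis.values
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = (x - x.mean()) / 700.0
            coeffs = rng.uniform(-0.5, 0.5, 3)
            background = 80.0 * (1.0 + coeffs[0] * t + coeffs[1] * t**2 + coeffs[2] * t**3)
            amp = rng.uniform(50.0, 150.0)
            center = rng.uniform(600.0, 1600.0)
            s = cm.Spectrum(axis, background + lorentzian(x, center, 12.0, amp))
            resid = cm.subtract_baseline(s, cm.BaselineRecipe())
            k = np.argmin(np.abs(x - center))
            errors.append(abs(resid.intensities[k] - amp) / amp)
        assert np.median(errors) < 0.05


class TestImageSubtraction:
    @pytest.fixture
    def small_img(self):
        axis = cm.SpectralAxis(np.arange(400.0, 700.0))
        rng = np.random.default_rng(3)
        cube = 10.0 + rng.normal(size=(3, 4, len(axis)))
        return cm.HyperspectralImage(axis, cube)

    def test_uniform_image_gives_uniform_output(self):
        axis = cm.SpectralAxis(np.arange(400.0, 700.0))
        pixel = 5.0 + 0.02 * axis.values
        cube = np.broadcast_to(pixel, (2, 3, len(axis))).copy()
        out = cm.subtract_baseline_image(
            cm.HyperspectralImage(axis, cube), cm.BaselineRecipe()
        )
        for r in range(2):
            for c in range(3):
                np.testing.assert_array_equal(out.cube[r, c], out.cube[0, 0])

    def test_single_pixel_equals_spectrum_path(self, small_img):
        one = cm.HyperspectralImage(small_img.axis, small_img.cube[:1, :1])
        rec = cm.BaselineRecipe()
        img_out = cm.subtract_baseline_image(one, rec)
        spec_out = cm.subtract_baseline(one.pixel(0, 0), rec)
        np.testing.assert_array_equal(img_out.cube[0, 0], spec_out.intensities)

    def test_pixel_permutation_commutes(self, small_img):
        """One shared recipe: no per-pixel adaptation."""
        rec = cm.BaselineRecipe()
        out = cm.subtract_baseline_image(small_img, rec)
        rng = np.random.default_rng(0)
        H, W, K = small_img.cube.shape
        perm = rng.permutation(H * W)
        shuffled = cm.HyperspectralImage(
            small_img.axis, small_img.cube.reshape(-1, K)[perm].reshape(H, W, K)
        )
        out_shuffled = cm.subtract_baseline_image(shuffled, rec)
        np.testing.assert_array_equal(
            out_shuffled.cube.reshape(-1, K), out.cube.reshape(-1, K)[perm]
        )


class TestSuggestRecipe:
    def _samples(self, n=3):
        axis = cm.SpectralAxis(np.arange(400.0, 1001.0))
        return [
            cm.Spectrum(axis, 10.0 + 0.05 * axis.values + float(i))
            for i in range(n)
        ]

    def test_singleton_grid(self):
        rec = cm.BaselineRecipe(smoothness=123.0)
        assert cm.suggest_recipe(self._samples(), [rec]) is rec

    def test_flatter_residual_wins(self):
        # degree-0 polynomial leaves the slope; ALS flattens it
        sloppy = cm.BaselineRecipe(method="polynomial-through-anchors", degree=0)
        good = cm.BaselineRecipe()
        assert cm.suggest_recipe(self._samples(), [sloppy, good]) is good

    def test_tie_returns_first(self):
        a = cm.BaselineRecipe()
        b = cm.BaselineRecipe()
        assert cm.suggest_recipe(self._samples(), [a, b]) is a

    def test_empty_grid_errors(self):
        with pytest.raises(cm.SpectralError):
            cm.suggest_recipe(self._samples(), [])

    def test_needs_two_spectra(self):
        with pytest.raises(cm.SpectralError):
            cm.suggest_recipe(self._samples(1), [cm.BaselineRecipe()])

    def test_default_grid_is_nonempty_and_valid(self):
        grid = default_recipe_grid()
        assert len(grid) >= 4
        assert all(isinstance(r, cm.BaselineRecipe) for r in grid)


def test_recipe_serialization_round_trip():
    rec = cm.BaselineRecipe(
        method="polynomial-through-anchors", anchors=(500.0, 900.0), degree=2
    )
    assert cm.BaselineRecipe.from_dict(rec.to_dict()) == rec


def test_recipe_validation():
    with pytest.raises(cm.SpectralError):
        cm.BaselineRecipe(asymmetry=1.5)
    with pytest.raises(cm.SpectralError):
        cm.BaselineRecipe(iterations=0)
    with pytest.raises(cm.SpectralError):
        cm.BaselineRecipe(method="rolling-ball")
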