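import numpy as np
import pytest

import cellmap as cm
from cellmap.phantom import COMPARTMENTS, NUCLEUS


class TestAiryRadius:
    def test_paper_geometry_full_width(self):
        assert cm.airy_radius(785.0, 0.5, "full-width") == pytest.approx(1.9154, abs=1e-4)

    def test_first_minimum_convention(self):
        assert cm.airy_radius(785.0, 0.5, "first-minimum") == pytest.approx(0.9577, abs=1e-4)

    @pytest.mark.parametrize("convention", ["first-minimum", "full-width"])
    def test_doubling_na_halves_radius(self, convention):
        r1 = cm.airy_radius(785.0, 0.4, convention)
        r2 = cm.airy_radius(785.0, 0.8, convention)
        assert r1 == pytest.approx(2.0 * r2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(cm.SpectralError):
            cm.airy_radius(785.0, 0.0)
        with pytest.raises(cm.SpectralError):
            cm.airy_radius(785.0, 2.0)
        with pytest.raises(cm.SpectralError):
            cm.airy_radius(-5.0, 0.5)
        with pytest.raises(cm.SpectralError):
            cm.airy_radius(785.0, 0.5, "fwhm")


class TestComponentLibrary:
    def test_dna_has_cytosine_line(self):
        dna = next(c for c in cm.default_library() if c.component == "DNA")
        assert 790.0 in {p[0] for p in dna.peaks}

    def test_heme_has_c_and_b_lines(self):
        heme = next(c for c in cm.default_library() if c.component == "heme")
        centers = {p[0] for p in heme.peaks}
        assert {750.0, 760.0} <= centers

    def test_no_line_in_noise_window(self):
        for comp in cm.default_library():
            for center, _, _, _ in comp.peaks:
                assert not 500.0 <= center <= 520.0

    def test_render_nonnegative_and_peaked(self):
        axis = cm.SpectralAxis(np.arange(400.0, 1801.0))
        dna = next(c for c in cm.default_library() if c.component == "DNA")
        y = dna.render(axis)
        assert y.min() >= 0
        assert abs(axis.values[np.argmax(y)] - 790.0) <= 1.0


class TestCompartmentProfiles:
    def test_nucleolus_richer_in_rna_than_nucleus(self):
        p = cm.compartment_profiles()
        assert p["nucleolus"]["RNA"] > p["nucleus"]["RNA"]

    def test_outside_has_only_substrate(self):
        p = cm.compartment_profiles()
        assert set(p["outside"]) == {"substrate"}

    def test_override_replaces_compartment(self):
        p = cm.compartment_profiles({"nucleus": {"DNA": 0.0}})
        assert p["nucleus"] == {"DNA": 0.0}

    def test_negative_weight_rejected(self):
        with pytest.raises(cm.SpectralError):
            cm.compartment_profiles({"nucleus": {"DNA": -1.0}})

    def test_all_zero_override_silent_phantom(self):
        overrides = {k: {} for k in COMPARTMENTS}
        params = cm.PhantomParams(
            profiles=overrides, noise_sigma=0.0, baseline_amplitude=0.0
        )
        ph = cm.generate_phantom(params, seed=0)
        assert np.max(np.abs(ph.image.cube)) == 0.0


class TestGeometry:
    def test_label_hierarchy(self):
        rng = np.random.default_rng(0)
        labels = cm.CellGeometry().label_image(rng)
        nuc = labels >= COMPARTMENTS["nucleus"]
        cell = labels > COMPARTMENTS["outside"]
        assert nuc.sum() > 0 and cell.sum() > nuc.sum()
        # nucleus strictly inside the cell; mitochondria never in the nucleus
        assert not (nuc & ~cell).any()
        assert not (labels == COMPARTMENTS["mitochondria"])[nuc].any()
        assert (labels == COMPARTMENTS["nucleolus"]).sum() > 0
        assert (labels == COMPARTMENTS["membrane"]).sum() > 0

    def test_cell_scale_matches_20um(self):
        rng = np.random.default_rng(0)
        geom = cm.CellGeometry()
        labels = geom.label_image(rng)
        cell_area_um2 = (labels > 0).sum() * geom.pixel_pitch_um**2
        equivalent_diameter = 2.0 * np.sqrt(cell_area_um2 / np.pi)
        assert 16.0 < equivalent_diameter < 24.0


class TestGeneratePhantom:
    def test_seed_determinism(self):
        params = cm.PhantomParams()
        a = cm.generate_phantom(params, seed=11)
        b = cm.generate_phantom(params, seed=11)
        np.testing.assert_array_equal(a.image.cube, b.image.cube)
        np.testing.assert_array_equal(a.hotspot_mask, b.hotspot_mask)

    def test_different_seed_differs(self):
        params = cm.PhantomParams()
        a = cm.generate_phantom(params, seed=1)
        b = cm.generate_phantom(params, seed=2)
        assert not np.array_equal(a.image.cube, b.image.cube)

    def test_single_pixel_generative_identity(self):
        """Noise-free full-coverage nucleus pixel = weighted component sum."""
        params = cm.PhantomParams(
            label_override=np.array([[NUCLEUS]], dtype=np.int8),
            hotspot=cm.HotspotModel(coverage=1.0),
            noise_sigma=0.0,
            baseline_amplitude=0.0,
            peak_amplitude=3.0,
        )
        ph = cm.generate_phantom(params, seed=0)
        axis = ph.image.axis
        from cellmap.phantom import _reference_height

        expected = np.zeros(len(axis))
        weights = cm.compartment_profiles()["nucleus"]
        att = params.hotspot.attenuation("nucleus")
        for comp in cm.default_library():
            w = weights.get(comp.component, 0.0)
            if w == 0.0:
                continue
            prof = comp.render(axis)
            prof = prof / _reference_height(comp, prof, axis)
            expected += 3.0 * w * att * prof
        np.testing.assert_allclose(ph.image.cube[0, 0], expected, rtol=1e-12)

    def test_no_signal_outside_hotspot(self):
        """The hotspot gate: a cell region off the aggregates is dark."""
        params = cm.PhantomParams(noise_sigma=0.0, baseline_amplitude=0.0)
        ph = cm.generate_phantom(params, seed=4)
        outside = ~ph.hotspot_mask
        # away from the blurred footprint edge the cube is strictly zero
        from scipy.ndimage import binary_dilation

        far_outside = outside & ~binary_dilation(ph.hotspot_mask, iterations=3)
        assert np.abs(ph.image.cube[far_outside]).max() < 1e-9

    def test_coverage_sampled_in_observed_range(self):
        for seed in range(5):
            ph = cm.generate_phantom(cm.PhantomParams(), seed=seed)
            assert 0.10 <= ph.hotspot_mask.mean() <= 0.73

    def test_short_axis_rejected(self):
        params = cm.PhantomParams(axis_start=600.0, axis_stop=1000.0)
        with pytest.raises(cm.SpectralError, match="too short"):
            cm.generate_phantom(params, seed=0)

    def test_attenuation_orders_by_membranes_crossed(self):
        hs = cm.HotspotModel()
        assert hs.attenuation("outside") == 1.0
        assert hs.attenuation("membrane") > hs.attenuation("nucleus")
        assert 0.9 < hs.attenuation("nucleus") < 1.0


class TestRecoveryProperties:
    def test_out_of_hotspot_ratio_near_one(self, default_phantom_run):
        """Pixels off the aggregates score ~1 in every imaging band."""
        ph, _, maps = default_phantom_run
        outside = ~ph.hotspot_mask
        for name, m in maps.items():
            mean_ratio = float(np.nanmean(m.values[outside]))
            assert 0.85 <= mean_ratio <= 1.15, name

    def test_dna_and_heme_maps_localize_compartments(self, default_phantom_run):
        ph, _, maps = default_phantom_run
        nuc = (ph.compartment_mask("nucleus") | ph.compartment_mask("nucleolus")) & ph.hotspot_mask
        mito = ph.compartment_mask("mitochondria") & ph.hotspot_mask
        r_dna = np.corrcoef(maps["DNA"].values.ravel(), nuc.ravel())[0, 1]
        r_heme = np.corrcoef(maps["heme"].values.ravel(), mito.ravel())[0, 1]
        assert r_dna > 0.6 and r_heme > 0.5  # strong localization signal
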