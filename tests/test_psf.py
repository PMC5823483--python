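import numpy as np
import pytest
import warnings
from hypothesis import given, settings, strategies as st

from subbandct import (
    BlurModel,
    FanBeamGeometry,
    ImageGrid,
    KernelWidthModel,
    build_subband_partition,
    estimate_rod_sigma,
    fit_kernel_width_model,
    load_scanner_rod_widths,
    make_rod_phantom,
    measurements_to_image_units,
    project,
    project_blurred,
    sigma_at,
    subband_masks,
)
from subbandct.psf import SubbandPartition, band_index_map


def _exact_pairs(coef, xs):
    a, b, c, d, e = coef
    return [(x, (a * x**2 + b * x + c) / (d * x + e)) for x in xs]


class TestKernelWidthModel:
    def test_constant_width_model(self):
        """Constant measurements admit the flat solution σ(x) = s."""
        pairs = [(x, 0.7) for x in (450.0, 530.0, 600.0, 670.0, 750.0)]
        m = fit_kernel_width_model(pairs)
        xs = np.linspace(455, 745, 20)
        assert np.allclose(sigma_at(m, xs), 0.7, atol=1e-9)

    def test_recovers_generating_coefficients_at_held_out_x(self):
        """Self-consistency: exact pairs from a known model predict held-out x."""
        coef = (1e-6, 1e-3, 0.2, 0.0, 1.0)
        xs = (450.0, 530.0, 600.0, 670.0, 750.0)
        m = fit_kernel_width_model(_exact_pairs(coef, xs), valid_range_mm=(450, 750))
        held_out = np.array([470.0, 615.0, 730.0])
        truth = [(coef[0] * x**2 + coef[1] * x + coef[2]) for x in held_out]
        assert np.allclose(sigma_at(m, held_out), truth, rtol=1e-6)

    def test_too_few_distinct_distances_rejected(self):
        pairs = [(500.0, 1.0), (500.0, 1.0), (600.0, 0.8), (700.0, 0.6)]
        with pytest.raises(ValueError, match="distinct"):
            fit_kernel_width_model(pairs)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(0, 2e-6),
        b=st.floats(0, 2e-3),
        c=st.floats(0.05, 1.0),
        d=st.floats(0, 5e-4),
    )
    def test_gauge_invariance_on_representable_data(self, a, b, c, d):
        """Both gauges give the same σ(x) when the data fit the model exactly."""
        coef = (a, b, c, d, 1.0)
        xs = (450.0, 500.0, 560.0, 620.0, 690.0, 750.0)
        pairs = _exact_pairs(coef, xs)
        m1 = fit_kernel_width_model(pairs, "e_fixed_1", valid_range_mm=(450, 750))
        m2 = fit_kernel_width_model(pairs, "unit_norm", valid_range_mm=(450, 750))
        xh = np.linspace(455, 745, 31)
        p1, p2 = sigma_at(m1, xh), sigma_at(m2, xh)
        assert np.allclose(p1, p2, rtol=1e-9, atol=1e-12)

    def test_sigma_at_trivial_models(self):
        flat = KernelWidthModel(0, 0, 2.0, 0, 1.0)
        assert sigma_at(flat, 123.0) == pytest.approx(2.0)
        line = KernelWidthModel(0, 1.0, 0, 0, 1.0)
        assert sigma_at(line, 600.0) == pytest.approx(600.0)

    def test_sigma_at_outside_valid_range_rejected(self):
        m = KernelWidthModel(0, 0, 1.0, 0, 1.0, valid_range_mm=(400.0, 800.0))
        with pytest.raises(ValueError, match="valid range"):
            sigma_at(m, 399.0)

    def test_json_round_trip(self):
        m = KernelWidthModel(1e-6, 1e-3, 0.2, 0.0, 1.0, "pixel", "e_fixed_1", (400.0, 800.0))
        assert KernelWidthModel.from_json(m.to_json()) == m

    def test_scanner_fixture_loads_and_reports_its_pathology(self):
        """The shipped scanner widths load; their printed pairing is non-monotone
        in source distance and the exact rational solve develops a pole inside
        the FOV, which the fit reports by contract (named crossing point)."""
        data = load_scanner_rod_widths()
        assert len(data["offsets_cm"]) == 5
        assert data["sigma"] == [0.1, 0.4, 0.95, 1.0, 1.1]
        d_iso = 600.0
        pairs = [
            (d_iso + 10.0 * off, sig)
            for off, sig in zip(data["offsets_cm"], data["sigma"])
        ]
        with pytest.raises(ValueError, match="vanishes near x = 62"):
            fit_kernel_width_model(pairs, valid_range_mm=(440, 760))


class TestSubbandPartition:
    def test_single_band_covers_fov_distance_range(self):
        g = FanBeamGeometry(n_channels=240)
        m = KernelWidthModel(0, 0, 1.0, 0, 1.0, valid_range_mm=(0, 2000))
        p = build_subband_partition(m, g, n=1)
        d, r = g.source_isocenter_mm, g.fov_radius_mm
        assert p.n_subbands == 1
        assert p.band_edges_mm[0] == pytest.approx(d - r)
        assert p.band_edges_mm[-1] == pytest.approx(d + r)

    def test_eleven_bands_default_operating_point(self):
        g = FanBeamGeometry(n_channels=240)
        m = KernelWidthModel(0, 0, 1.0, 0, 1.0, valid_range_mm=(0, 2000))
        p = build_subband_partition(m, g, n=11)
        assert p.n_subbands == 11
        assert np.allclose(np.diff(p.band_edges_mm), np.diff(p.band_edges_mm)[0])

    def test_decreasing_model_gives_decreasing_band_sigmas(self):
        g = FanBeamGeometry(n_channels=240)
        m = KernelWidthModel(0, -1e-3, 1.5, 0, 1.0, valid_range_mm=(0, 1400))
        p = build_subband_partition(m, g, n=8)
        assert np.all(np.diff(p.band_sigmas) < 0)

    def test_round_trip_band_sigmas(self):
        g = FanBeamGeometry(n_channels=240)
        m = KernelWidthModel(1e-7, -1e-3, 1.2, 0, 1.0, valid_range_mm=(0, 1400))
        p = build_subband_partition(m, g, n=11)
        assert np.array_equal(p.band_sigmas, np.atleast_1d(sigma_at(m, p.band_centers_mm)))

    def test_model_range_must_cover_fov(self):
        g = FanBeamGeometry(n_channels=240)
        m = KernelWidthModel(0, 0, 1.0, 0, 1.0, valid_range_mm=(550.0, 650.0))
        with pytest.raises(ValueError, match="valid range"):
            build_subband_partition(m, g, n=11)

    def test_json_round_trip(self):
        p = SubbandPartition(np.array([500.0, 600.0, 700.0]), np.array([1.0, 0.5]))
        q = SubbandPartition.from_json(p.to_json())
        assert np.array_equal(q.band_edges_mm, p.band_edges_mm)
        assert np.array_equal(q.band_sigmas, p.band_sigmas)


@pytest.fixture(scope="module")
def mask_setup(small_geometry, small_grid):
    m = KernelWidthModel(0, 0, 1.0, 0, 1.0, valid_range_mm=(0, 2000))
    return small_geometry, small_grid, m


class TestSubbandMasks:

    @pytest.mark.parametrize("n", [1, 2, 11])
    def test_masks_partition_fov_disk_every_view(self, mask_setup, n):
        g, grid, m = mask_setup
        part = build_subband_partition(m, g, n)
        fov = grid.radius_map() <= g.fov_radius_mm
        for v in range(0, g.n_views, 23):
            masks = subband_masks(part, g, grid, v)
            union = np.zeros_like(fov)
            overlap = np.zeros(fov.shape, dtype=int)
            for mask in masks:
                union |= mask
                overlap += mask
            assert np.array_equal(union, fov)
            assert overlap.max() <= 1

    def test_isocenter_band_is_view_invariant(self, mask_setup):
        """L = D at the isocenter for every view, so its band never changes."""
        g, grid, m = mask_setup
        part = build_subband_partition(m, g, 11)
        center = grid.index_of(0.0, 0.0)
        indices = {
            int(band_index_map(part, g, grid, v)[center]) for v in range(g.n_views)
        }
        assert len(indices) == 1

    def test_offcenter_pixel_visits_multiple_bands(self, mask_setup):
        """A pixel at 60 mm sweeps L over ≈120 mm, spanning several 13 mm bands."""
        g, grid, m = mask_setup
        part = build_subband_partition(m, g, 11)
        px = grid.index_of(0.0, -60.0)
        indices = {
            int(band_index_map(part, g, grid, v)[px]) for v in range(g.n_views)
        }
        assert len(indices) >= 2


class TestEstimateRodSigma:
    def test_five_rod_battery_yields_five_measurements(self, small_geometry):
        """The five-offset design gives one measurement per rod, with distinct
        source distances under the signed-offset convention."""
        offsets = [0.0, 35.0, 60.0, -35.0, -60.0]
        sinos = [
            project(make_rod_phantom([o], geometry=small_geometry), small_geometry)
            for o in offsets
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = estimate_rod_sigma(sinos, offsets)
        assert len(ms) == 5
        dists = [m.distance_from_source_mm for m in ms]
        assert len(set(np.round(dists, 1))) == 5
        # positive offsets lie beyond the isocenter distance
        assert dists[1] > dists[0] > dists[3]

    def test_unblurred_rod_reports_discretization_floor(self, small_geometry):
        sino = project(make_rod_phantom([0.0], geometry=small_geometry), small_geometry)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (m,) = estimate_rod_sigma([sino], [0.0])
        assert m.sigma <= 0.2

    def test_known_blur_recovered(self, small_geometry):
        blur = BlurModel("distance_dependent", widths=[1.5], n_depth_bands=1)
        sino = project_blurred(
            make_rod_phantom([0.0], geometry=small_geometry), small_geometry, blur
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (m,) = estimate_rod_sigma([sino], [0.0])
        assert m.sigma == pytest.approx(1.5, rel=0.1)

    def test_empty_sinogram_rejected(self, small_geometry):
        from subbandct.projector import Sinogram

        sino = Sinogram(np.zeros((180, 240)), small_geometry)
        with pytest.raises(ValueError, match="usable"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimate_rod_sigma([sino], [0.0])

    def test_channel_to_pixel_conversion(self, small_geometry):
        """σ_px = σ_ch · Δγ · x / pixel size."""
        from subbandct.psf import PSFMeasurement

        m = PSFMeasurement(0.0, 600.0, 2.0, "channel")
        (c,) = measurements_to_image_units([m], small_geometry, pixel_mm=0.5)
        expected = 2.0 * small_geometry.delta_gamma_rad * 600.0 / 0.5
        assert c.sigma == pytest.approx(expected)
        assert c.width_unit == "pixel"
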