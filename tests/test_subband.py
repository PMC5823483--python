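import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import fftconvolve

from subbandct import (
    DeconvSpec,
    KernelWidthModel,
    add_noise,
    build_subband_partition,
    fbp,
    gaussian_kernel_2d,
    project,
    regularized_deconvolve,
    subband_backproject_view,
    subband_reconstruct,
    weight_and_filter,
)
from subbandct.fbp import RampFilter, backproject_view
from subbandct.projector import Sinogram
from subbandct.psf import SubbandPartition
from subbandct.subband import _BandDeconvolver


def _zero_model():
    return KernelWidthModel(0, 0, 0, 0, 1.0, valid_range_mm=(0.0, 2000.0))


def _linear_model():
    # decreasing width, ~1.5 px near the source side of the FOV
    return KernelWidthModel(0, -2.0e-3, 2.4, 0, 1.0, valid_range_mm=(0.0, 1400.0))


class TestGaussianKernel:
    def test_zero_sigma_identity(self):
        assert np.array_equal(gaussian_kernel_2d(0.0), [[1.0]])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(sigma=st.floats(0.1, 6.0))
    def test_taps_sum_to_one(self, sigma):
        assert gaussian_kernel_2d(sigma).sum() == pytest.approx(1.0, abs=1e-12)

    def test_central_tap_matches_continuous_density(self):
        sigma = 2.0
        k = gaussian_kernel_2d(sigma)
        center = k[k.shape[0] // 2, k.shape[1] // 2]
        assert center == pytest.approx(1.0 / (2 * np.pi * sigma**2), rel=0.01)

    def test_support_and_oddness(self):
        k = gaussian_kernel_2d(1.5, truncation=4.0)
        assert k.shape[0] % 2 == 1
        assert k.shape[0] >= 2 * 4.0 * 1.5 + 1


class TestRegularizedDeconvolve:
    def test_identity_kernel_zero_lambda(self):
        rng = np.random.default_rng(1)
        img = rng.random((48, 48))
        out = regularized_deconvolve(img, np.array([[1.0]]), 0.0)
        assert np.allclose(out, img, rtol=1e-8, atol=1e-12)

    def test_constant_image_any_kernel_any_lambda(self):
        """DC gain is exactly 1: the Laplacian penalty has no DC response."""
        const = np.full((40, 40), 2.5)
        for lam in (1e-3, 1e-1):
            out = regularized_deconvolve(const, gaussian_kernel_2d(2.0), lam)
            assert np.allclose(out, 2.5, rtol=1e-8)
        # λ = 0 needs a kernel whose response stays clear of underflow
        out = regularized_deconvolve(const, gaussian_kernel_2d(1.0), 0.0)
        assert np.allclose(out, 2.5, rtol=1e-8)

    def test_restoration_gain_on_blurred_pattern(self):
        """Blur-then-deconvolve with the true kernel wins decisively over no-op."""
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        truth = gaussian_filter((rng.random((128, 128)) < 0.5).astype(float), 1.0)
        k = gaussian_kernel_2d(2.0)
        pad = 16
        blurred = fftconvolve(np.pad(truth, pad, mode="symmetric"), k, mode="same")
        blurred = blurred[pad:-pad, pad:-pad]
        restored = regularized_deconvolve(blurred, k, 1e-3)
        rmse = lambda a: np.sqrt(np.mean((a - truth) ** 2))
        assert rmse(restored) <= (2.0 / 3.0) * rmse(blurred)

    def test_zero_lambda_with_vanishing_response_rejected(self):
        img = np.zeros((64, 64))
        wide = gaussian_kernel_2d(4.0)  # response underflows at high frequency
        with pytest.raises(ValueError, match="ill-posed"):
            regularized_deconvolve(img, wide, 0.0)


class TestSubbandReconstruct:
    def test_zero_width_model_reduces_to_fbp(
        self, small_geometry, small_grid, two_disk_phantom
    ):
        sino = project(two_disk_phantom, small_geometry)
        ref = fbp(sino, small_grid).values
        for n in (1, 11):
            part = build_subband_partition(_zero_model(), small_geometry, n)
            rec = subband_reconstruct(sino, small_grid, part).values
            assert np.allclose(rec, ref, rtol=1e-6, atol=1e-6 * np.abs(ref).max())

    def test_single_band_equals_global_deconvolution(
        self, small_geometry, small_grid, two_disk_phantom
    ):
        """n = 1 collapses to deconvolving each whole view backprojection."""
        sigma0 = 1.2
        part = SubbandPartition(
            np.array([small_geometry.source_isocenter_mm - small_geometry.fov_radius_mm,
                      small_geometry.source_isocenter_mm + small_geometry.fov_radius_mm]),
            np.array([sigma0]),
        )
        sino = project(two_disk_phantom, small_geometry)
        filtered = weight_and_filter(sino, RampFilter())
        spec = DeconvSpec()
        via_subband = subband_backproject_view(filtered, 7, part, small_grid, spec)
        bp = backproject_view(filtered, 7, small_grid)
        direct = regularized_deconvolve(
            bp, gaussian_kernel_2d(sigma0, spec.kernel_truncation),
            spec.regularization_lambda,
        )
        fov = small_grid.radius_map() <= small_geometry.fov_radius_mm
        assert np.allclose(via_subband[fov], direct[fov], rtol=1e-6, atol=1e-12)

    def test_all_bands_below_threshold_pass_through(
        self, small_geometry, small_grid, two_disk_phantom
    ):
        part = build_subband_partition(
            KernelWidthModel(0, 0, 0.1, 0, 1.0, valid_range_mm=(0, 2000)),
            small_geometry,
            5,
        )
        sino = project(two_disk_phantom, small_geometry)
        filtered = weight_and_filter(sino, RampFilter())
        out = subband_backproject_view(filtered, 3, part, small_grid)
        bp = backproject_view(filtered, 3, small_grid)
        assert np.allclose(out, bp, atol=1e-9)

    def test_feather_differs_only_near_band_boundaries(
        self, small_geometry, small_grid, two_disk_phantom
    ):
        part = build_subband_partition(_linear_model(), small_geometry, 4)
        sino = project(two_disk_phantom, small_geometry)
        filtered = weight_and_filter(sino, RampFilter())
        hard = subband_backproject_view(filtered, 0, part, small_grid, DeconvSpec())
        feather = subband_backproject_view(
            filtered, 0, part, small_grid, DeconvSpec(blend="feather", feather_width_px=4.0)
        )
        diff = np.abs(hard - feather)
        beta = small_geometry.view_angles_rad[0]
        x, y = small_grid.pixel_coordinates()
        length, _ = small_geometry.fan_coordinates(beta, x, y)
        # distance (mm) from the nearest interior band edge
        interior_edges = np.asarray(part.band_edges_mm[1:-1])
        edge_dist = np.min(np.abs(length[..., None] - interior_edges), axis=-1)
        far = edge_dist > 4.0 * small_grid.pixel_mm / 2 + small_grid.pixel_mm
        assert np.all(diff[far] == 0.0)

    def test_linearity_in_sinogram(self, small_geometry, small_grid, two_disk_phantom):
        part = build_subband_partition(_linear_model(), small_geometry, 5)
        sino = project(two_disk_phantom, small_geometry)
        r1 = subband_reconstruct(sino, small_grid, part).values
        r2 = subband_reconstruct(
            Sinogram(2.0 * sino.values, small_geometry), small_grid, part
        ).values
        assert np.allclose(r2, 2.0 * r1, rtol=1e-9, atol=1e-12)

    def test_precomputed_band_responses_match_direct_deconvolution(self, small_grid):
        """The cached per-band transfers equal per-call regularized_deconvolve."""
        part = SubbandPartition(
            np.array([500.0, 550.0, 600.0, 650.0]), np.array([2.0, 1.0, 0.5])
        )
        spec = DeconvSpec()
        rng = np.random.default_rng(5)
        img = rng.random((small_grid.n_pixels, small_grid.n_pixels))
        dec = _BandDeconvolver(part, img.shape, spec)
        band_imgs = dec.band_images(img)
        for sigma, got in zip(part.band_sigmas, band_imgs):
            k = gaussian_kernel_2d(float(sigma), spec.kernel_truncation)
            # same padded FFT shape => identical to within FFT round-off
            direct = regularized_deconvolve(img, k, spec.regularization_lambda)
            assert np.allclose(got, direct, atol=2e-10)

    def test_noise_monotonicity_with_lambda(
        self, small_geometry, small_grid, two_disk_phantom
    ):
        """Weaker regularization boosts image noise (the trade-off the subband
        count manages)."""
        part = build_subband_partition(_linear_model(), small_geometry, 5)
        sino = add_noise(project(two_disk_phantom, small_geometry), 2e4, seed=11)
        stds = []
        fov_flat = small_grid.radius_map() < 12.0  # flat interior of the big disk
        for lam in (1e-1, 1e-2, 1e-3):
            rec = subband_reconstruct(
                sino, small_grid, part, spec=DeconvSpec(regularization_lambda=lam)
            )
            stds.append(rec.values[fov_flat].std())
        assert stds[0] <= stds[1] <= stds[2]

    def test_channel_unit_partition_rejected(self, small_geometry, small_grid, two_disk_phantom):
        part = SubbandPartition(np.array([500.0, 700.0]), np.array([1.0]), "channel")
        sino = project(two_disk_phantom, small_geometry)
        with pytest.raises(ValueError, match="pixel"):
            subband_reconstruct(sino, small_grid, part)
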