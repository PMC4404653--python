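import numpy as np
import pytest

from stalkscan.bundlesize import (
    bundle_sizes,
    extract_patch,
    fit_gaussian2d,
    homomorphic_filter,
)
from stalkscan.io import Calibration


def render_gaussian(shape, center, sa, sb, theta, amp, baseline=20.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = yy - center[0], xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    qa = (dr * ct + dc * st) / sa
    qb = (-dr * st + dc * ct) / sb
    return baseline + amp * np.exp(-0.5 * (qa**2 + qb**2))


class TestExtractPatch:
    def test_interior_patch_is_plain_slice(self):
        img = np.arange(300 * 300, dtype=float).reshape(300, 300)
        patch, clipped = extract_patch(img, (100, 100), size=40)
        assert not clipped
        assert np.array_equal(patch, img[80:120, 80:120])

    def test_edge_patch_reflected_and_flagged(self):
        img = np.arange(100 * 100, dtype=float).reshape(100, 100)
        patch, clipped = extract_patch(img, (5, 5), size=40)
        assert clipped
        assert patch.shape == (40, 40)

    @pytest.mark.parametrize("size", [7, 6, 4])
    def test_bad_size_rejected(self, size):
        img = np.zeros((100, 100))
        with pytest.raises(ValueError):
            extract_patch(img, (50, 50), size=size)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError):
            extract_patch(np.zeros((50, 50)), (60, 10))


class TestHomomorphicFilter:
    def test_constant_patch_stays_constant(self):
        out = homomorphic_filter(np.full((40, 40), 90.0))
        assert np.allclose(out, out[0, 0])

    def test_identity_transfer_is_monotone_rescaling(self):
        rng = np.random.default_rng(0)
        patch = rng.uniform(10, 200, (40, 40))
        out = homomorphic_filter(patch, gain_low=1.0, gain_high=1.0)
        # out must be a strictly increasing linear map of patch
        flat_in, flat_out = patch.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= -1e-9).all()
        corr = np.corrcoef(flat_in, flat_out)[0, 1]
        assert corr > 0.999999

    @staticmethod
    def _illum_and_bump(img):
        """(amplitude of the period-40 illumination cosine, bump contrast)."""
        prof = img.mean(axis=0)
        c = np.cos(2 * np.pi * np.arange(40) / 40)
        illum_amp = abs(2 * (prof * c).mean())
        inner = img[16:25, 16:25].mean()
        ring = np.concatenate([img[4:6, 4:36].ravel(), img[34:36, 4:36].ravel()])
        return illum_amp, inner - ring.mean()

    def test_illumination_suppressed_relative_to_bump(self):
        """Low-frequency illumination shrinks relative to the bundle bump.

        The output is min-max rescaled, so the meaningful quantity is the
        illumination-to-bump amplitude ratio: it must drop under the
        default gains, drop monotonically as gain_low decreases, and fall
        by more than 70% under strong suppression (gain_low = 0.05).
        """
        yy, xx = np.mgrid[0:40, 0:40]
        illum = 1 + 0.4 * np.cos(2 * np.pi * xx / 40)
        bump = render_gaussian((40, 40), (20, 20), 4, 4, 0, 60, baseline=0)
        patch = illum * 80.0 + bump
        i0, b0 = self._illum_and_bump(patch)
        ratios = []
        for gain_low in (0.5, 0.2, 0.05):
            i1, b1 = self._illum_and_bump(homomorphic_filter(patch, gain_low=gain_low))
            assert b1 > 0  # bump survives
            ratios.append((i1 / b1) / (i0 / b0))
        assert ratios[0] < 0.8  # default gains already suppress
        assert ratios[0] > ratios[1] > ratios[2]  # monotone in gain_low
        assert ratios[2] < 0.3  # strong setting: >70% reduction

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            homomorphic_filter(np.full((10, 10), -1.0))


class TestFitGaussian:
    def test_noiseless_parameter_recovery(self):
        patch = render_gaussian((40, 40), (20.3, 19.6), 5.0, 3.0, 0.4, 100.0)
        fit = fit_gaussian2d(patch)
        assert fit.converged
        assert fit.sigma_major == pytest.approx(5.0, rel=0.01)
        assert fit.sigma_minor == pytest.approx(3.0, rel=0.01)
        assert fit.theta == pytest.approx(0.4, abs=0.02)
        assert fit.amplitude == pytest.approx(100.0, rel=0.01)

    def test_isotropic_blob_area_is_two_sigma_ellipse(self):
        patch = render_gaussian((40, 40), (20, 20), 4.0, 4.0, 0.0, 80.0)
        fit = fit_gaussian2d(patch)
        assert fit.converged
        assert fit.area_px2 == pytest.approx(np.pi * 8 * 8, rel=0.005)

    def test_pure_noise_not_converged(self):
        rng = np.random.default_rng(3)
        patch = rng.uniform(0, 255, (40, 40))
        fit = fit_gaussian2d(patch)
        assert not fit.converged
        assert np.isnan(fit.area_px2)

    def test_constant_patch_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian2d(np.full((40, 40), 5.0))

    def test_rotation_invariance(self):
        patch = render_gaussian((40, 40), (20, 20), 5.0, 2.5, 0.3, 90.0)
        fit_a = fit_gaussian2d(patch)
        fit_b = fit_gaussian2d(np.rot90(patch).copy())
        assert fit_a.converged and fit_b.converged
        assert fit_a.area_px2 == pytest.approx(fit_b.area_px2, rel=0.005)

    def test_batch_recovery_noiseless_and_noisy(self):
        """Seeded random blobs: <1% sigma error clean, <10% median
        area error at 5% amplitude noise."""
        rng = np.random.default_rng(12345)
        max_rel_err = 0.0
        noisy_area_errs = []
        for _ in range(60):
            sa = rng.uniform(2.5, 6.0)
            sb = sa * rng.uniform(0.5, 1.0)
            theta = rng.uniform(-np.pi / 2, np.pi / 2)
            amp = rng.uniform(50, 150)
            center = (20 + rng.uniform(-3, 3), 20 + rng.uniform(-3, 3))
            patch = render_gaussian((40, 40), center, sa, sb, theta, amp)
            fit = fit_gaussian2d(patch)
            assert fit.converged
            max_rel_err = max(
                max_rel_err,
                abs(fit.sigma_major - sa) / sa,
                abs(fit.sigma_minor - sb) / sb,
            )
            noisy = patch + rng.normal(0, 0.05 * amp, patch.shape)
            nfit = fit_gaussian2d(np.clip(noisy, 0, None))
            if nfit.converged:
                true_area = np.pi * (2 * sa) * (2 * sb)
                noisy_area_errs.append(abs(nfit.area_px2 - true_area) / true_area)
        assert max_rel_err < 0.01
        assert len(noisy_area_errs) > 54
        assert np.median(noisy_area_errs) < 0.10


class TestBundleSizes:
    def test_mean_area_of_identical_blobs(self):
        cal = Calibration(px_per_cm=315.0)
        img = np.full((600, 600), 20.0)
        centers = []
        for i in range(5):
            for j in range(10):
                c = (60 + 100 * i, 30 + 55 * j)
                img += render_gaussian(img.shape, c, 4.0, 4.0, 0.0, 80.0, baseline=0)
                centers.append(c)
        fits, mean_area = bundle_sizes(img, centers, cal, enhance=False)
        assert sum(f.converged for f in fits) == 50
        expected = np.pi * 8 * 8 / 315.0**2
        assert mean_area == pytest.approx(expected, rel=0.01)

    def test_uniform_background_center_excluded(self):
        cal = Calibration(px_per_cm=315.0)
        img = np.full((200, 200), 20.0)
        img += render_gaussian(img.shape, (60, 60), 4, 4, 0, 80, baseline=0)
        fits, mean_area = bundle_sizes(img, [(60, 60), (150, 150)], cal, enhance=False)
        assert fits[0].converged
        assert not fits[1].converged
        assert np.isfinite(mean_area)

    def test_empty_centers_no_summary(self):
        cal = Calibration(px_per_cm=315.0)
        fits, mean_area = bundle_sizes(np.zeros((100, 100)), [], cal)
        assert fits == []
        assert np.isnan(mean_area)

    def test_area_scales_with_calibration(self):
        img = np.full((100, 100), 10.0)
        img += render_gaussian(img.shape, (50, 50), 4, 3, 0.2, 90, baseline=0)
        _, a1 = bundle_sizes(img, [(50, 50)], Calibration(px_per_cm=100.0), enhance=False)
        _, a2 = bundle_sizes(img, [(50, 50)], Calibration(px_per_cm=200.0), enhance=False)
        assert a1 == pytest.approx(4 * a2, rel=1e-9)
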