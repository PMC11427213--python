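"""Bandpass-wavelet-Fourier destriping: bands, filtering, auto-sigma, ECR."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from silmas import (
    AUTO_SIGMA,
    BandpassWaveletConfig,
    StripeSpec,
    add_stripes,
    auto_sigma,
    destripe_plane,
    energy_change_ratio,
    split_bands,
    wavelet_fourier_filter_band,
)
from silmas.destripe import FALLBACK_SIGMA, gaussian_smooth
from silmas.wavelets import get_wavelet

from conftest import column_mean_variance, column_peak_to_trough, two_region_plane


class TestSplitBands:
    def test_constant_image(self):
        img = np.full((64, 64), 42.0)
        ratios, residual = split_bands(img, (15, 61))
        for r in ratios:
            np.testing.assert_allclose(r, 1.0, rtol=1e-12)
        np.testing.assert_allclose(residual, 42.0, rtol=1e-12)

    def test_multiplicative_reconstruction_identity(self, rng):
        img = rng.uniform(10, 1000, (128, 128))
        for sizes in [(15,), (15, 61)]:
            ratios, residual = split_bands(img, sizes)
            rec = residual.copy()
            for r in ratios:
                rec = rec * r
            np.testing.assert_allclose(rec, img, rtol=1e-6)

    def test_band_energy_partition(self):
        # slow ramp lands in the residual, fine checkerboard in the first band
        y, x = np.mgrid[0:128, 0:128]
        ramp = 500.0 + 2.0 * x
        checker = 50.0 * ((-1.0) ** (x + y))
        img = ramp + checker
        ratios, residual = split_bands(img, (15, 61))
        # oracle: direct Gaussian filtering with the same kernels
        smooth1 = gaussian_smooth(img, 15)
        np.testing.assert_allclose(ratios[0], img / smooth1, rtol=1e-9)
        band1_signal = ratios[0] - 1.0
        checker_rel = checker / smooth1
        corr = np.corrcoef(band1_signal.ravel(), checker_rel.ravel())[0, 1]
        assert corr > 0.99  # checkerboard energy is concentrated in band 1
        inner = np.s_[20:-20, 20:-20]
        resid_err = np.abs(residual - ramp)[inner].max() / ramp[inner].mean()
        assert resid_err < 0.02  # ramp survives into the residual

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            split_bands(np.full((8, 8), -1.0), (5,))


class TestWaveletFourierFilterBand:
    @pytest.mark.parametrize("wavelet", ["db4", "db45"])
    def test_disabled_damping_is_identity(self, rng, wavelet):
        img = rng.normal(100, 10, (128, 128))
        out = wavelet_fourier_filter_band(
            img, [1, 2, 3], wavelet, sigma=5.0, damping_fn=lambda n, s: np.ones(n)
        )
        np.testing.assert_allclose(out, img, rtol=1e-8, atol=1e-8 * np.abs(img).max())

    def test_horizontal_structure_untouched(self):
        # constant along the stripe-normal axis -> zero vertical detail
        img = np.tile(np.linspace(100, 200, 128)[:, None], (1, 128))
        out = wavelet_fourier_filter_band(img, [1, 2, 3, 4], "db8", sigma=10.0)
        np.testing.assert_allclose(out, img, rtol=1e-8)

    def test_flat_field_stripe_suppression(self):
        img = add_stripes(np.full((256, 256), 1000.0), [StripeSpec(128, 8, 0.3)])
        out = wavelet_fourier_filter_band(
            img, list(range(1, 8)), "db45", sigma=AUTO_SIGMA
        )
        full = np.ones((256, 256), bool)
        before = column_peak_to_trough(img, full)
        after = column_peak_to_trough(out, full)
        assert after <= 0.1 * before

    def test_infeasible_level_error_names_max(self):
        with pytest.raises(ValueError, match="feasible depth"):
            wavelet_fourier_filter_band(np.ones((8, 8)), [20], "db1", sigma=1.0)

    @pytest.mark.parametrize("wavelet", ["db4", "db16", "db38", "db45"])
    @pytest.mark.parametrize("level", [1, 4, 6])
    def test_perfect_reconstruction_property(self, rng, wavelet, level):
        """Decompose/recompose with no damping is the identity for all wavelets."""
        import pywt

        img = rng.normal(1000, 100, (96, 96))
        wav = get_wavelet(wavelet)
        with pytest.warns(UserWarning) if False else np.errstate():
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coeffs = pywt.wavedec2(img, wav, mode="symmetric", level=level)
                rec = pywt.waverec2(coeffs, wav, mode="symmetric")
        np.testing.assert_allclose(rec[:96, :96], img, rtol=1e-8)


class TestAutoSigma:
    def test_straight_stripes_give_narrow_sigma(self):
        img = add_stripes(np.full((256, 256), 1000.0), [StripeSpec(128, 8, 0.3)])
        for width in (4, 8, 16):
            img_w = add_stripes(np.full((256, 256), 1000.0), [StripeSpec(128, width, 0.3)])
            sig = auto_sigma(img_w, [1, 2], "db8")
            # straight stripes concentrate at zero stripe-axis frequency
            # regardless of width: the damping needs only a narrow band
            assert all(1.0 <= s <= 2.0 for s in sig.values())

    def test_wandering_stripes_need_wider_sigma(self):
        rng = np.random.default_rng(5)
        walk = gaussian_filter1d(np.cumsum(rng.normal(0, 1, 256)), 8)
        walk = (walk - walk.mean()) / walk.std()
        x = np.arange(256)[None, :]
        straight = 1000.0 * (1 - 0.3 * np.exp(-(((x - 128) / 4.0) ** 4)))
        straight = np.tile(straight, (256, 1))
        c = 128 + 8.0 * walk[:, None]
        wavy = 1000.0 * (1 - 0.3 * np.exp(-(((x - c) / 4.0) ** 4)))
        s_straight = auto_sigma(straight, [1], "db8")[1]
        s_wavy = auto_sigma(wavy, [1], "db8")[1]
        assert s_wavy > 1.5 * s_straight

    def test_white_noise_within_sanity_bounds(self, rng):
        import pywt

        plane = rng.normal(0, 1, (256, 256))
        sig = auto_sigma(plane, [1], "db8")[1]
        n_coeff = pywt.wavedec2(plane, "db8", mode="symmetric", level=1)[1][1].shape[0]
        assert 1.0 <= sig <= n_coeff / 4.0

    def test_all_zero_band_falls_back(self):
        sig = auto_sigma(np.zeros((64, 64)), [1], "db4")
        assert sig[1] == FALLBACK_SIGMA


class TestDestripePlane:
    def test_stripe_free_constant_is_identity(self):
        img = np.full((128, 128), 42.0)
        cfg = BandpassWaveletConfig(gauss_sizes=(15.0, 61.0), dec_levels=((1, 2), (1, 2, 3)))
        np.testing.assert_allclose(destripe_plane(img, cfg), img, rtol=1e-12)

    def test_mask_merge_keeps_background_bit_identical(self, rng):
        img = add_stripes(np.full((128, 128), 1000.0), [StripeSpec(40, 8, 0.3)])
        img = img + rng.normal(0, 5, img.shape) ** 2  # non-negative noise floor
        mask = np.zeros((128, 128), bool)
        mask[:, :64] = True
        cfg = BandpassWaveletConfig(gauss_sizes=(15.0,), dec_levels=((1, 2, 3),))
        out = destripe_plane(img, cfg, tissue_mask=mask)
        np.testing.assert_array_equal(out[:, 64:], img[:, 64:])
        assert not np.array_equal(out[:, :64], img[:, :64])

    def _disc_hole_phantom(self):
        ny = nx = 512
        Y, X = np.mgrid[0:ny, 0:nx]
        img = np.full((ny, nx), 1000.0)
        disc = (Y - 170) ** 2 + (X - 170) ** 2 < 80**2
        hole = (Y - 340) ** 2 + (X - 340) ** 2 < 40**2
        img[disc] = 4000.0
        img[hole] = 100.0
        specs = [
            StripeSpec(c, w, 0.3, 4)
            for c, w in [(60, 4), (128, 16), (200, 4), (290, 16), (340, 4), (380, 4), (450, 16)]
        ]
        return add_stripes(img, specs), ~(disc | hole), disc, hole

    def test_bandpass_is_safe_in_dark_region(self):
        """Adding a second band must not increase dark-region stripe energy
        relative to the single-band filter, while stripes are suppressed in
        all three intensity regions."""
        striped, mid, disc, hole = self._disc_hole_phantom()
        two = BandpassWaveletConfig(
            gauss_sizes=(15.0, 61.0), dec_levels=((1, 2, 3), (1, 2, 3, 4, 5, 6))
        )
        one = BandpassWaveletConfig(gauss_sizes=(15.0,), dec_levels=((1, 2, 3, 4, 5, 6),))
        f2 = destripe_plane(striped, two)
        f1 = destripe_plane(striped, one)
        for region in (mid, disc, hole):
            assert column_mean_variance(f2, region) < column_mean_variance(striped, region)
        assert column_mean_variance(f2, hole) <= column_mean_variance(f1, hole)

    def test_single_band_degenerates_to_plain_filtering(self, rng):
        img = add_stripes(np.full((128, 128), 1000.0), [StripeSpec(64, 8, 0.3)])
        cfg = BandpassWaveletConfig(gauss_sizes=(15.0,), dec_levels=((1, 2, 3),), sigma=2.0)
        ratios, residual = split_bands(img, (15.0,), cfg.eps_frac)
        expected = residual * np.exp(
            wavelet_fourier_filter_band(
                np.log(np.maximum(ratios[0], cfg.eps_frac)), (1, 2, 3), "db45", 2.0
            )
        )
        np.testing.assert_allclose(destripe_plane(img, cfg), expected, rtol=1e-10)


class TestEnergyChangeRatio:
    @pytest.mark.parametrize(
        "orig,filt,expected",
        [
            ([3.0, 4.0], [3.0, 4.0], 0.0),
            ([3.0, 4.0], [0.0, 0.0], 1.0),
            ([3.0, 4.0], [3.0, 0.0], 0.64),
        ],
    )
    def test_two_pixel_cases(self, orig, filt, expected):
        assert energy_change_ratio(np.array(orig), np.array(filt)) == pytest.approx(expected)

    def test_zero_original_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            energy_change_ratio(np.zeros(4), np.ones(4))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            energy_change_ratio(np.zeros((2, 2)), np.zeros((2, 3)))


class TestTradeoffMonotonicity:
    @staticmethod
    def _wandering_striped_plane():
        rng = np.random.default_rng(3)
        ny = nx = 512
        walk = gaussian_filter1d(np.cumsum(rng.normal(0, 1, ny)), 8)
        walk = (walk - walk.mean()) / walk.std()
        x = np.arange(nx)[None, :]
        img = np.full((ny, nx), 1000.0)
        for c0, w in [(60, 4), (128, 16), (200, 4), (290, 16), (380, 4), (450, 16)]:
            c = c0 + 6.0 * walk[:, None]
            img = img * (1 - 0.3 * np.exp(-np.abs((x - c) / (w / 2.0)) ** 4))
        return img + rng.normal(0, 15, img.shape)

    def test_ecr_nondecreasing_in_sigma_linear_path(self):
        """Wider Fourier damping removes strictly more on a fixed striped input."""
        img = self._wandering_striped_plane()
        ecrs = [
            energy_change_ratio(
                img, wavelet_fourier_filter_band(img, [1, 2, 3, 4], "db8", s)
            )
            for s in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
        ]
        assert all(b > a for a, b in zip(ecrs, ecrs[1:]))

    def test_ecr_nondecreasing_in_sigma_and_levels_end_to_end(self):
        img = self._wandering_striped_plane()
        base_cfg = dict(gauss_sizes=(15.0, 61.0))
        ecr_sigma = []
        for sigma in (2.0, 8.0, 32.0):
            cfg = BandpassWaveletConfig(
                dec_levels=((1, 2, 3), (1, 2, 3, 4)), sigma=sigma, **base_cfg
            )
            ecr_sigma.append(energy_change_ratio(img, destripe_plane(img, cfg)))
        # multiplicative band recombination allows sub-percent wiggles
        assert all(b >= a * (1 - 1e-2) for a, b in zip(ecr_sigma, ecr_sigma[1:]))
        assert ecr_sigma[-1] > 1.5 * ecr_sigma[0]
        ecr_depth = []
        for depth in (2, 4, 6):
            cfg = BandpassWaveletConfig(
                dec_levels=(tuple(range(1, depth + 1)),) * 2, sigma=3.0, **base_cfg
            )
            ecr_depth.append(energy_change_ratio(img, destripe_plane(img, cfg)))
        assert all(b >= a * (1 - 1e-2) for a, b in zip(ecr_depth, ecr_depth[1:]))
        assert ecr_depth[-1] > 1.5 * ecr_depth[0]

    def test_stripe_axis_specificity(self):
        # purely horizontal structure (constant along the stripe axis)
        img = np.tile(500.0 + 400.0 * np.sin(np.arange(256) / 9.0)[:, None], (1, 256))
        img = np.abs(img) + 10.0
        cfg = BandpassWaveletConfig(
            gauss_sizes=(15.0, 61.0), dec_levels=((1, 2, 3), (1, 2, 3, 4)), sigma=3.0
        )
        out = destripe_plane(img, cfg)
        assert energy_change_ratio(img, out) < 1e-6


class TestConfigValidation:
    def test_defaults_follow_heuristics(self):
        cfg = BandpassWaveletConfig()
        assert cfg.wavelet == "db45"  # high-order Daubechies default
        assert list(cfg.gauss_sizes) == sorted(cfg.gauss_sizes)
        assert cfg.sigma == AUTO_SIGMA

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(gauss_sizes=()),
            dict(gauss_sizes=(61.0, 15.0)),
            dict(gauss_sizes=(15.0, 15.0)),
            dict(gauss_sizes=(15.0,), dec_levels=((1,), (2,))),
            dict(gauss_sizes=(15.0,), dec_levels=((0,),)),
            dict(gauss_sizes=(15.0,), dec_levels=((1,),), sigma=-5.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BandpassWaveletConfig(**kwargs)
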