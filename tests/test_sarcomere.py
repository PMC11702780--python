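"""Rectangle + two-half-Gaussian band fitting and TFL/SL measurement."""

import math

import numpy as np
import pytest

from nebquant import sarcomere as sc
from nebquant.simulate import ProfileSimConfig, gen_line_profile

W, SIGMA, A, B = 1.72, 0.16986, 100.0, 10.0


def single_band_profile(center=3.0, width=W, sigma=SIGMA, amplitude=A, baseline=B,
                        spacing=0.02, extent=3.0):
    x = np.arange(center - extent, center + extent + spacing / 2, spacing)
    y = sc.band_model(x, center, width, sigma, sigma, amplitude, baseline)
    return sc.LineProfile(positions=x, intensities=y)


class TestBandModel:
    def test_plateau_center_and_baseline_limit(self):
        assert sc.band_model(3.0, 3.0, W, SIGMA, SIGMA, A, B) == pytest.approx(B + A)
        assert sc.band_model(1e6, 3.0, W, SIGMA, SIGMA, A, B) == pytest.approx(B)
        assert sc.band_model(-1e6, 3.0, W, SIGMA, SIGMA, A, B) == pytest.approx(B)

    def test_half_maximum_at_hwhm_from_plateau_edge(self):
        x = 3.0 - W / 2 - SIGMA * math.sqrt(2 * math.log(2))
        assert sc.band_model(x, 3.0, W, SIGMA, SIGMA, A, B) == pytest.approx(B + A / 2)

    def test_continuity_at_plateau_edges(self):
        for edge in (3.0 - W / 2, 3.0 + W / 2):
            inside = sc.band_model(edge, 3.0, W, SIGMA, SIGMA, A, B)
            just_out = sc.band_model(edge + math.copysign(1e-13, edge - 3.0),
                                     3.0, W, SIGMA, SIGMA, A, B)
            assert abs(inside - just_out) < 1e-9

    def test_asymmetric_sigmas(self):
        left = sc.band_model(3.0 - W / 2 - 0.2, 3.0, W, 0.1, 0.3, A, 0.0)
        right = sc.band_model(3.0 + W / 2 + 0.2, 3.0, W, 0.1, 0.3, A, 0.0)
        assert right > left  # broader right edge decays slower


class TestDetectBands:
    def test_three_band_centers_recovered(self):
        profile, truth = gen_line_profile(ProfileSimConfig(), seed=0)
        centers = sc.detect_bands(profile)
        assert len(centers) == 3
        assert np.all(np.abs(centers - np.array(truth["centers"])) < 0.2)

    def test_flat_profile_raises(self):
        flat = sc.LineProfile(np.arange(0, 1, 0.02), np.full(50, 7.0))
        with pytest.raises(ValueError, match="no maxima|flat"):
            sc.detect_bands(flat)

    def test_single_band(self):
        profile = single_band_profile()
        (center,) = sc.detect_bands(profile)
        assert center == pytest.approx(3.0, abs=0.2)


class TestFitBand:
    def test_noiseless_recovery_within_1e4_relative(self):
        profile = single_band_profile(width=1.52)
        band = sc.fit_band(profile, center0=3.05)
        truth = {"center": 3.0, "width": 1.52, "sigma_left": SIGMA,
                 "sigma_right": SIGMA, "amplitude": A, "baseline": B}
        for name, val in truth.items():
            assert getattr(band, name) == pytest.approx(val, rel=1e-4, abs=1e-6), name

    def test_masking_defeats_central_bump(self):
        cfg = ProfileSimConfig(n_bands=1, bump_height=0.3, bump_fwhm=0.1, noise_sigma=0.0)
        profile, truth = gen_line_profile(cfg, seed=0)
        two_pass = sc.fit_band(profile, center0=truth["centers"][0])
        assert two_pass.width == pytest.approx(W, rel=0.02)
        assert len(two_pass.masked_indices) > 0
        # an unmasked single-pass fit must not beat the masked one
        unmasked = sc.fit_band(profile, center0=truth["centers"][0],
                               config=sc.BandFitConfig(mask_fraction=0.0))
        assert abs(two_pass.width - W) <= abs(unmasked.width - W) + 1e-12

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        x = np.arange(0, 6, 0.02)
        noisy = sc.LineProfile(x, 10 + rng.standard_normal(x.size))
        with pytest.raises((sc.BandFitError, ValueError)):
            sc.fit_band(noisy, center0=3.0)

    def test_center_outside_range_rejected(self):
        with pytest.raises(ValueError):
            sc.fit_band(single_band_profile(), center0=99.0)


class TestTflFromFit:
    @pytest.mark.parametrize("width,expected", [(1.72, 1.06), (1.52, 0.96)])
    def test_wt_and_hom_worked_examples(self, width, expected):
        band = sc.FittedBand(center=0.0, width=width, sigma_left=SIGMA,
                             sigma_right=SIGMA, amplitude=A, baseline=B, residual_ss=0.0)
        assert sc.tfl_from_fit(band) == pytest.approx(expected, abs=5e-5)

    def test_vanishing_edge_spread_limit(self):
        band = sc.FittedBand(center=0.0, width=2.0, sigma_left=1e-12, sigma_right=1e-12,
                             amplitude=1.0, baseline=0.0, residual_ss=0.0)
        assert sc.tfl_from_fit(band) == pytest.approx(1.0)

    def test_sigma_sides_are_averaged(self):
        band = sc.FittedBand(center=0.0, width=1.0, sigma_left=0.1, sigma_right=0.3,
                             amplitude=1.0, baseline=0.0, residual_ss=0.0)
        fwhm = 2 * math.sqrt(2 * math.log(2)) * 0.2
        assert sc.tfl_from_fit(band) == pytest.approx(0.5 + fwhm / 2)


def _band_at(center):
    return sc.FittedBand(center=center, width=1.0, sigma_left=0.1, sigma_right=0.1,
                         amplitude=1.0, baseline=0.0, residual_ss=0.0)


class TestSlAndFilter:
    def test_consecutive_center_differences(self):
        sls = sc.sl_from_fits([_band_at(c) for c in (0.0, 2.6, 5.2)])
        assert sls == pytest.approx([2.6, 2.6])

    def test_single_band_raises(self):
        with pytest.raises(ValueError):
            sc.sl_from_fits([_band_at(0.0)])

    def test_order_independent_and_positive(self):
        centers = [5.2, 0.0, 2.6]
        sls = sc.sl_from_fits([_band_at(c) for c in centers])
        assert np.all(sls > 0)
        assert sls == pytest.approx([2.6, 2.6])

    def test_window_inclusive_boundaries(self):
        meas = [sc.SarcomereMeasurement(i, 1.0, sl) for i, sl in
                enumerate([2.3, 2.4, 2.8, 2.9])]
        kept = sc.filter_by_sl(meas, sc.SlWindow())
        assert [m.sl for m in kept] == [2.4, 2.8]

    def test_empty_and_identity(self):
        assert sc.filter_by_sl([], sc.SlWindow()) == []
        inside = [sc.SarcomereMeasurement(0, 1.0, 2.5)]
        assert sc.filter_by_sl(inside, sc.SlWindow()) == inside

    def test_generated_sl_recovered(self):
        profile, truth = gen_line_profile(ProfileSimConfig(sl=2.5), seed=1)
        bands = sc.fit_profile(profile)
        assert sc.sl_from_fits(bands) == pytest.approx([2.5, 2.5], abs=0.02)


class TestRoundTrip:
    def test_noiseless_tfl_recovery_across_parameter_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            w = rng.uniform(1.2, 2.2)
            s = rng.uniform(0.1, 0.25)
            sl = max(2.6, w + 4 * s + 0.3)
            cfg = ProfileSimConfig(width=w, sigma=s, sl=sl)
            profile, truth = gen_line_profile(cfg, seed=int(rng.integers(2**31)))
            _, meas = sc.analyze_profile(profile, window=sc.SlWindow(0.5 * sl, 2.0 * sl))
            assert meas, "no measurements retained"
            for m in meas:
                assert abs(m.tfl - truth["tfl"]) < 1e-3

    def test_tfl_invariant_to_translation_and_intensity_scale(self):
        profile, truth = gen_line_profile(ProfileSimConfig(n_bands=1), seed=0)
        base = sc.tfl_from_fit(sc.fit_band(profile, truth["centers"][0]))
        shifted = sc.LineProfile(profile.positions + 13.7, profile.intensities)
        scaled = sc.LineProfile(profile.positions, 3.5 * profile.intensities)
        tfl_shift = sc.tfl_from_fit(sc.fit_band(shifted, truth["centers"][0] + 13.7))
        tfl_scale = sc.tfl_from_fit(sc.fit_band(scaled, truth["centers"][0]))
        assert tfl_shift == pytest.approx(base, abs=1e-6)
        assert tfl_scale == pytest.approx(base, abs=1e-6)


class TestLineProfileValidation:
    def test_rejects_short_nonuniform_or_unsorted(self):
        with pytest.raises(ValueError):
            sc.LineProfile(np.arange(5.0), np.arange(5.0))
        x = np.arange(0, 1, 0.02).copy()
        x[10] += 0.005
        with pytest.raises(ValueError):
            sc.LineProfile(x, np.zeros_like(x))


def test_extract_line_profile_averages_across_width():
    img = np.tile(np.linspace(0, 10, 64), (16, 1))  # horizontal ramp
    prof = sc.extract_line_profile(img, start=(8, 2), end=(8, 60), pixel_size=0.1,
                                   line_width=3, n_samples=32)
    assert prof.positions[0] == 0.0
    assert prof.positions[-1] == pytest.approx(5.8)
    assert np.all(np.diff(prof.intensities) > 0)
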