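"""Polar conversion, residual/density profiles, error counts, summaries."""

import math

import numpy as np
import pytest

import mirrortrace as mt
from mirrortrace.errors import SummaryError
from mirrortrace.metrics import (AngularProfile, boxcox_z, count_errors,
                                 density_profile, density_profile_legacy,
                                 path_to_polar, residual, residual_profile,
                                 summarize)
from mirrortrace.simulate import PatternSpec, generate_drawing
from mirrortrace.star import render_expected_star

from conftest import make_bump_image


class TestPolarConvention:
    def test_top_is_zero_right_is_ninety(self, band512):
        band = mt.StarBand(shape=band512.shape, r_ext=band512.r_ext,
                           r_int=band512.r_int, center=(256.0, 256.0))
        mask = np.zeros((512, 512), dtype=bool)
        mask[56, 256] = True   # directly above center
        mask[256, 456] = True  # directly right of center
        tr = path_to_polar(mask, band)
        degs = sorted(np.degrees(tr.phi))
        assert degs[0] == pytest.approx(0.0, abs=1e-9)
        assert degs[1] == pytest.approx(90.0, abs=1e-9)

    def test_radius_is_euclidean_distance(self, band512):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 512, 1000)
        cols = rng.integers(0, 512, 1000)
        mask = np.zeros((512, 512), dtype=bool)
        mask[rows, cols] = True
        tr = path_to_polar(mask, band512)
        coords = np.argwhere(mask)
        oracle = np.hypot(coords[:, 0] - band512.center[0],
                          coords[:, 1] - band512.center[1])
        np.testing.assert_allclose(np.sort(tr.r), np.sort(oracle), rtol=1e-12)

    def test_empty_path_gives_empty_trace(self, band512):
        tr = path_to_polar(np.zeros((512, 512), dtype=bool), band512)
        assert len(tr) == 0


class TestResidual:
    def test_identities_on_ideal_and_contours(self, band512):
        phi = np.random.default_rng(1).uniform(0, 2 * np.pi, 100)
        f = mt.star_radius(phi, band512.shape)
        assert np.allclose(residual(phi, band512.r_mid * f, band512), 0.0)
        assert np.allclose(residual(phi, band512.r_ext * f, band512), 0.5)
        assert np.allclose(residual(phi, band512.r_int * f, band512), -0.5)

    def test_scale_invariance_of_binned_residuals(self, band1024):
        """The same drawing rendered at x1/x2/x3 gives matching profiles."""
        profiles = []
        for s, th in [(1, 5), (2, 9), (3, 13)]:
            size = 1024 * s
            band = mt.StarBand(shape=band1024.shape,
                               r_ext=band1024.r_ext * s,
                               r_int=band1024.r_int * s,
                               center=((size - 1) / 2.0,) * 2)
            img, _ = generate_drawing(
                PatternSpec(pattern="oscillation", amplitude=0.25,
                            frequency=8, radial_noise_sd=0.0, theta=th,
                            seed=0), band, (size, size))
            tr = path_to_polar(img.path_mask, band)
            profiles.append(residual_profile(tr, 1.0, "mean"))
        assert np.nanmax(np.abs(profiles[0] - profiles[1])) < 0.02
        assert np.nanmax(np.abs(profiles[0] - profiles[2])) < 0.02

    def test_sign_convention_for_offset_traces(self, band512):
        for pattern, check in [("offset_out", lambda v: np.all(v > 0)),
                               ("offset_in", lambda v: np.all(v < 0))]:
            img, _ = generate_drawing(
                PatternSpec(pattern=pattern, offset=0.3, radial_noise_sd=0.0,
                            seed=0), band512, (512, 512))
            prof = residual_profile(path_to_polar(img.path_mask, band512))
            assert check(prof[~np.isnan(prof)])


class TestDensity:
    def test_expected_star_self_normalizes_exactly(self, band512):
        mask = render_expected_star(band512, 5, (512, 512))
        rho = density_profile(mask, band512, 5)
        assert rho.shape == (360,)
        assert (rho == 1.0).all()

    def test_empty_path_gives_zero_density(self, band512):
        rho = density_profile(np.zeros((512, 512), dtype=bool), band512, 5)
        assert (rho == 0.0).all()

    def test_double_trace_doubles_density(self, band512):
        """A second radially offset pass over an arc doubles rho there."""
        from mirrortrace.simulate import _stamp
        from mirrortrace.star import polar_to_pixel

        base = render_expected_star(band512, 5, (512, 512))
        arc = np.linspace(math.radians(120), math.radians(130), 4000)
        r = mt.ideal_radius(arc, band512) + 7.0
        row, col = polar_to_pixel(r, arc, band512.center)
        second = _stamp(np.stack([row, col], axis=1), 5, (512, 512))
        rho = density_profile(base | second, band512, 5)
        covered = slice(121, 129)
        assert np.all(np.abs(rho[covered] - 2.0) < 0.35)
        untouched = np.r_[rho[:118], rho[133:]]
        assert np.all(np.abs(untouched - 1.0) < 0.25)

    def test_pen_thickness_invariance(self, band1024):
        rhos = {}
        for th in (3, 7):
            img, _ = generate_drawing(
                PatternSpec(pattern="ideal", theta=th, radial_noise_sd=0.0,
                            seed=0), band1024, (1024, 1024))
            est = mt.estimate_thickness(img.path_mask)
            rhos[th] = density_profile(img.path_mask, band1024, est)
        assert np.max(np.abs(rhos[3] - rhos[7])) < 0.15

    def test_legacy_density_shows_corner_artifact(self, band512, star512):
        """Area normalization varies over bins where the new density is 1."""
        mask = render_expected_star(band512, 5, (512, 512))
        rho_old = density_profile_legacy(mask, star512.band_mask, band512, 5)
        assert rho_old.std() / rho_old.mean() > 0.1
        assert (density_profile(mask, band512, 5) == 1.0).all()

    def test_legacy_wedge_arithmetic(self):
        """40 path px over band area 200 at theta 2 gives 0.1 (single bin)."""
        band = mt.StarBand(shape=mt.StarShape(k=0.0), r_ext=40.0, r_int=20.0,
                           center=(50.0, 50.0))
        band_mask = np.zeros((101, 101), dtype=bool)
        band_mask[np.argwhere(np.ones((101, 101)))[:200, 0] // 101,
                  np.argwhere(np.ones((101, 101)))[:200, 0] % 101] = False
        # place 200 band pixels and 40 path pixels anywhere: one 360-deg bin
        band_mask[10, 0:40] = True
        band_mask[11, 0:40] = True
        band_mask[12, 0:40] = True
        band_mask[13, 0:40] = True
        band_mask[14, 0:40] = True
        path = np.zeros_like(band_mask)
        path[30, 0:40] = True
        rho = density_profile_legacy(path, band_mask, band, theta=2,
                                     bin_width_deg=360.0)
        assert rho.shape == (1,)
        assert rho[0] == pytest.approx(40 / (200 * 2))


class TestResidualProfile:
    def test_constant_residual_statistics(self, band512):
        phi = np.random.default_rng(0).uniform(0, 2 * np.pi, 5000)
        c = -0.27
        tr = mt.PolarTrace(r=np.zeros_like(phi), phi=phi,
                           residual=np.full_like(phi, c))
        assert np.allclose(residual_profile(tr, 1.0, "mean")[
            ~np.isnan(residual_profile(tr, 1.0, "mean"))], c)
        got_abs = residual_profile(tr, 1.0, "mean_abs")
        assert np.allclose(got_abs[~np.isnan(got_abs)], abs(c))
        got_sq = residual_profile(tr, 1.0, "mean_sq")
        assert np.allclose(got_sq[~np.isnan(got_sq)], c ** 2)

    def test_two_pixel_bin_arithmetic(self):
        tr = mt.PolarTrace(r=np.zeros(2), phi=np.radians([10.2, 10.7]),
                           residual=np.array([-0.2, 0.4]))
        assert residual_profile(tr, 1.0, "mean")[10] == pytest.approx(0.1)
        assert residual_profile(tr, 1.0, "mean_abs")[10] == pytest.approx(0.3)
        assert residual_profile(tr, 1.0, "mean_sq")[10] == pytest.approx(0.1)

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(50, 500)
            phi = rng.uniform(0, 2 * np.pi, n)
            res = rng.normal(0, 0.4, n)
            tr = mt.PolarTrace(r=np.zeros(n), phi=phi, residual=res)
            got = residual_profile(tr, 1.0, "mean")
            for b in range(360):
                sel = (np.degrees(phi) >= b) & (np.degrees(phi) < b + 1)
                if sel.any():
                    assert got[b] == pytest.approx(res[sel].mean())
                else:
                    assert np.isnan(got[b])

    def test_unknown_stat_rejected(self, band512):
        tr = mt.PolarTrace(r=np.zeros(1), phi=np.zeros(1),
                           residual=np.zeros(1))
        with pytest.raises(ValueError):
            residual_profile(tr, 1.0, "median")


class TestCountErrors:
    def test_trace_in_band_has_no_errors(self, ideal_drawing):
        img, _ = ideal_drawing
        assert count_errors(img) == 0

    def test_two_outward_excursions(self, band512, star512):
        img = make_bump_image(band512, star512, [90, 200], +1)
        assert count_errors(img) == 2

    def test_four_inward_excursions(self, band512, star512):
        img = make_bump_image(band512, star512, [45, 135, 225, 315], -1)
        assert count_errors(img) == 4

    def test_translation_and_rotation_invariance(self, band512, star512):
        img = make_bump_image(band512, star512, [90, 200], +1)
        n0 = count_errors(img)
        rolled = mt.HarmonizedImage(
            path_mask=np.roll(img.path_mask, (5, -7), axis=(0, 1)),
            band_mask=np.roll(img.band_mask, (5, -7), axis=(0, 1)),
            border_mask=np.roll(img.border_mask, (5, -7), axis=(0, 1)))
        rotated = mt.HarmonizedImage(path_mask=np.rot90(img.path_mask),
                                     band_mask=np.rot90(img.band_mask),
                                     border_mask=np.rot90(img.border_mask))
        assert count_errors(rolled) == n0
        assert count_errors(rotated) == n0


class TestSummarize:
    @staticmethod
    def _profile(density, mean_residual):
        n = len(density)
        return AngularProfile(bin_width_deg=360.0 / n,
                              density=np.asarray(density, dtype=float),
                              mean_residual=np.asarray(mean_residual,
                                                       dtype=float),
                              mean_abs_residual=np.abs(mean_residual),
                              mean_sq_residual=np.square(mean_residual),
                              n_pixels=np.ones(n, dtype=int),
                              band_area_px=np.ones(n, dtype=int))

    def test_mean_density_arithmetic(self):
        s = summarize(self._profile([1, 2, 1, 1], [0.1, 0.1, 0.1, 0.1]),
                      errors=0, time_s=None, theta=3)
        assert s.mean_density == pytest.approx(1.25)

    def test_sum_vs_mean_scaling_factor(self):
        prof = self._profile(np.ones(360), np.full(360, 0.2))
        s = summarize(prof, 0, None, 3)
        assert s.sum_sq_residuals == pytest.approx(
            360 * np.mean(prof.mean_residual ** 2))

    def test_expected_star_path_is_near_perfect(self, band512):
        mask = render_expected_star(band512, 5, (512, 512))
        img = mt.HarmonizedImage(path_mask=mask,
                                 band_mask=np.zeros_like(mask),
                                 border_mask=np.zeros_like(mask))
        prof = mt.angular_profile(img, band512, 5)
        s = summarize(prof, 0, None, 5)
        assert s.mean_density == 1.0
        assert s.sum_sq_residuals <= 0.36

    def test_all_missing_bins_rejected(self):
        prof = self._profile(np.zeros(4), [np.nan] * 4)
        with pytest.raises(SummaryError):
            summarize(prof, 0, None, 3)


class TestBoxCoxZ:
    def test_standardization_contract(self):
        rng = np.random.default_rng(0)
        z, _ = boxcox_z(rng.lognormal(0, 1, 200))
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(7)
        _, lmbda = boxcox_z(rng.lognormal(0, 1, 500))
        assert -0.2 < lmbda < 0.2

    def test_normal_sample_lambda_near_one(self):
        rng = np.random.default_rng(11)
        v = rng.normal(50, 5, 500)
        z, lmbda = boxcox_z(v)
        plain = (v - v.mean()) / v.std(ddof=0)
        assert abs(lmbda - 1) < 0.35
        assert np.corrcoef(z, plain)[0, 1] > 0.999

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            boxcox_z([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            boxcox_z([1.0, 2.0])
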