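"""Diffraction PSF, transfer functions and optical filtering."""

import numpy as np
import pytest
import scipy.ndimage

from acuitysim import psf as P
from acuitysim.eye import monochromatic_weighting, chromatic_model
from acuitysim.wavefront import (SubjectRecord, build_opd, defocus_coefficient,
                                 diopters_from_coefficient, pupil_function)


def test_frequency_resolution_identity():
    g = P.DEFAULT_GRID
    assert g.df_cpd == pytest.approx(0.6142, abs=5e-5)
    assert g.df_cpd == pytest.approx(1.0 / (g.n * g.dx_deg))


def _bare_pupil(d_mm, lam_nm, grid, opd_coeffs=None):
    """Pupil with uniform transmission (no Stiles-Crawford) on the grid's
    wavelength-matched pupil pitch."""
    sp = grid.pupil_spacing_mm(lam_nm)
    s = SubjectRecord("t", 0, 0, d_mm, d_mm, opd_coeffs or {})
    opd = build_opd(s, d_mm, grid.n, sp)
    return pupil_function(opd, np.ones_like(opd), lam_nm,
                          spacing_mm=sp, diameter_mm=d_mm)


class TestMonochromaticPSF:
    def test_unit_surface_integral(self, mid_grid):
        psf = P.monochromatic_psf(_bare_pupil(5.0, 555.0, mid_grid), mid_grid)
        assert psf.integral == pytest.approx(1.0, abs=1e-9)
        assert np.all(psf.values >= 0)

    def test_airy_first_zero_position(self, mid_grid):
        # unapodized circular pupil: first dark ring at 1.22 lambda/d
        d_mm, lam = 5.0, 555.0
        psf = P.monochromatic_psf(_bare_pupil(d_mm, lam, mid_grid), mid_grid)
        c = mid_grid.n // 2
        profile = psf.values[c, c:c + 10]
        expected_px = (1.22 * lam * 1e-9 / (d_mm * 1e-3)) / mid_grid.dx_rad
        k = np.argmin(profile[2:9]) + 2
        # parabolic sub-pixel refinement around the minimum
        y0, y1, y2 = profile[k - 1: k + 2]
        frac = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
        assert k + frac == pytest.approx(expected_px, abs=0.35)

    def test_tilt_translates_psf_without_reshaping(self, small_grid):
        lam = 555.0
        sp = small_grid.pupil_spacing_mm(lam)
        s = SubjectRecord("t", 0, 0, 4.0, 4.0, {})
        opd = build_opd(s, 4.0, small_grid.n, sp)
        t_amp = np.ones_like(opd)
        base = P.monochromatic_psf(
            pupil_function(opd, t_amp, lam, spacing_mm=sp, diameter_mm=4.0),
            small_grid)
        # linear phase of exactly k pixels of angular shift:
        # OPD = x * shift_rad / lambda (in lambda0 units at lambda0)
        k_px = 7
        x = (np.arange(small_grid.n) - small_grid.n // 2)[None, :] * sp  # mm
        shift_rad = k_px * small_grid.dx_rad
        tilt = (x * 1e-3) * shift_rad / (lam * 1e-9)
        tilted = P.monochromatic_psf(
            pupil_function(opd + tilt, t_amp, lam, spacing_mm=sp, diameter_mm=4.0),
            small_grid)
        rolled = np.roll(base.values, -k_px, axis=1)
        assert np.abs(tilted.values - rolled).max() < 1e-6 * base.values.max()

    def test_wrong_pupil_pitch_rejected(self, small_grid):
        pup = _bare_pupil(4.0, 555.0, small_grid)
        bad = P.PupilFunction(pup.values, pup.spacing_mm * 1.01, 4.0, 555.0)
        with pytest.raises(P.GridError):
            P.monochromatic_psf(bad, small_grid)


class TestPolychromaticPSF:
    def test_degenerate_weighting_equals_monochromatic(self, small_grid,
                                                       diffraction_limited_subject):
        s = SubjectRecord("t", 0, 0, 4.0, 4.0, {(3, -1): 0.1})
        mono = monochromatic_weighting()
        poly = P.polychromatic_psf(s, 4.0, mono, grid=small_grid)
        stack = P._PupilStack(s, 4.0, small_grid)
        direct = P.monochromatic_psf(stack.pupil(555.0), small_grid)
        assert poly.integral == pytest.approx(1.0, abs=1e-9)
        assert np.abs(poly.values - direct.values).max() < 1e-6 * direct.values.max()

    def test_chromatic_blur_broadens_psf(self, mid_grid, diffraction_limited_subject):
        s = SubjectRecord("t", 0, 0, 4.5, 4.5, {})
        chrom = chromatic_model()
        poly = P.polychromatic_psf(s, 4.5, chrom, grid=mid_grid)
        stack = P._PupilStack(s, 4.5, mid_grid)
        mono = P.monochromatic_psf(stack.pupil(555.0), mid_grid)
        assert poly.second_moment_deg2() > mono.second_moment_deg2()

    def test_weight_order_invariance(self, small_grid):
        from acuitysim.eye import ChromaticModel
        s = SubjectRecord("t", 0, 0, 4.0, 4.0, {(2, 2): 0.2})
        lams = np.array([500.0, 555.0, 610.0])
        w = np.array([0.25, 0.5, 0.25])
        dd = np.array([-0.3, 0.0, 0.2])
        a = P.polychromatic_psf(s, 4.0, ChromaticModel(lams, w, dd), grid=small_grid)
        perm = [2, 0, 1]
        b = P.polychromatic_psf(s, 4.0, ChromaticModel(lams[perm], w[perm], dd[perm]),
                                grid=small_grid)
        assert np.abs(a.values - b.values).max() < 1e-9 * a.values.max()


class TestOpticalFilter:
    def _delta_psf(self, grid):
        vals = np.zeros((grid.n, grid.n))
        vals[grid.n // 2, grid.n // 2] = 1.0 / grid.dx_deg ** 2
        return P.PSFImage(vals, grid)

    def test_delta_psf_is_identity(self, small_grid, rng):
        ii = (rng.random((small_grid.n, small_grid.n)) > 0.5).astype(float)
        ri = P.optical_filter(ii, self._delta_psf(small_grid))
        assert np.abs(ri - ii).max() < 1e-9

    def test_uniform_field_preserved(self, small_grid):
        psf = P.polychromatic_psf(SubjectRecord("t", 0, 0, 4.0, 4.0, {}),
                                  4.0, monochromatic_weighting(), grid=small_grid)
        ri = P.optical_filter(np.ones((small_grid.n, small_grid.n)), psf)
        assert np.abs(ri - 1.0).max() < 1e-9

    def test_mean_preserved(self, small_grid, rng):
        psf = P.polychromatic_psf(SubjectRecord("t", 0, 0, 4.0, 4.0, {(2, -2): 0.3}),
                                  4.0, monochromatic_weighting(), grid=small_grid)
        ii = (rng.random((small_grid.n, small_grid.n)) > 0.7).astype(float)
        ri = P.optical_filter(ii, psf)
        assert ri.mean() == pytest.approx(ii.mean(), abs=1e-9)

    def test_matches_spatial_convolution_oracle(self, rng):
        # small-grid equivalence with direct wrap-around convolution
        g = P.GridSpec(n=64, dx_arcsec=5.724)
        x = np.arange(64) - 32
        xx, yy = np.meshgrid(x, x)
        kern = np.exp(-(xx ** 2 + yy ** 2) / (2 * 2.5 ** 2))
        psf = P.PSFImage(kern / (kern.sum() * g.dx_deg ** 2), g)
        ii = rng.random((64, 64))
        ri = P.optical_filter(ii, psf)
        oracle = scipy.ndimage.convolve(ii, kern / kern.sum(), mode="wrap")
        assert np.abs(ri - oracle).max() < 1e-6


class TestBestFocus:
    def test_diffraction_limited_eye_already_focused(self):
        s = SubjectRecord("t", 0, 0, 5.0, 5.0, {})
        extra = P.best_focus(s, 5.0, monochromatic_weighting())
        assert abs(diopters_from_coefficient(extra, 5.0)) < 0.02

    def test_injected_defocus_recovered(self):
        inj_D = 0.25
        c20 = defocus_coefficient(inj_D, 5.0)
        s = SubjectRecord("t", 0, 0, 5.0, 5.0, {(2, 0): c20})
        extra = P.best_focus(s, 5.0, monochromatic_weighting())
        assert diopters_from_coefficient(extra, 5.0) == pytest.approx(-inj_D, abs=0.02)

    def test_myopic_path_keeps_stored_defocus(self):
        # stored negative defocus is excluded from the scan but not from
        # the subject record (the paraxial correction is removed afterwards)
        from acuitysim.io import fixture_subject
        s = fixture_subject("KM")
        assert s.coeffs[(2, 0)] == pytest.approx(-2.24)
        extra = P.best_focus(s, 6.0, monochromatic_weighting())
        assert s.coeffs[(2, 0)] == pytest.approx(-2.24)  # record untouched
        # the offset is small compared to the stored myopia
        assert abs(extra) < abs(s.coeffs[(2, 0)])
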