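"""Subject records, OPD maps, apodization and the pupil function."""

import numpy as np
import pytest

from acuitysim import zernike
from acuitysim.io import fixture_subject
from acuitysim.wavefront import (PupilExtrapolationWarning, SubjectRecord,
                                 build_opd, defocus_coefficient,
                                 diopters_from_coefficient, pupil_coordinates,
                                 pupil_function, stiles_crawford_T)


class TestSubjectRecord:
    def test_rejects_unphysiological_pupils(self):
        with pytest.raises(ValueError):
            SubjectRecord("x", 0, 0, -1.0, 5.0, {})
        with pytest.raises(ValueError):
            SubjectRecord("x", 0, 0, 5.0, 9.5, {})

    def test_rejects_piston_tilt_and_huge_coefficients(self):
        with pytest.raises(ValueError):
            SubjectRecord("x", 0, 0, 5.0, 5.0, {(0, 0): 0.5})
        with pytest.raises(ValueError):
            SubjectRecord("x", 0, 0, 5.0, 5.0, {(1, 1): 0.5})
        with pytest.raises(ValueError):
            SubjectRecord("x", 0, 0, 5.0, 5.0, {(2, 2): 11.0})

    def test_osa_view_matches_nm_keys(self):
        s = SubjectRecord("x", 0, 0, 5.0, 5.0, {(2, -2): 0.1, (4, 0): -0.2})
        assert s.coeffs_osa == {3: 0.1, 12: -0.2}


class TestBuildOpd:
    def test_zero_coefficients_give_flat_disc(self):
        s = SubjectRecord("x", 0, 0, 5.0, 5.0, {})
        opd = build_opd(s, 5.0, 128, 0.05)
        inside = ~np.isnan(opd)
        assert inside.any()
        assert np.allclose(opd[inside], 0.0)

    def test_single_mode_rms_equals_coefficient(self):
        # orthonormal modes: the RMS of the map over the disc is |c|
        c = 0.37
        s = SubjectRecord("x", 0, 0, 6.0, 6.0, {(3, -1): c})
        opd = build_opd(s, 6.0, 512, 6.0 / 500)
        inside = ~np.isnan(opd)
        assert np.sqrt((opd[inside] ** 2).mean()) == pytest.approx(c, rel=5e-3)

    def test_fixture_coefficients_recovered_by_refit(self):
        # least-squares Zernike re-fit of the sampled map returns the
        # Table coefficients (round-trip oracle)
        s = fixture_subject("ST")
        n = 256
        spacing = s.d_w_mm / (n - 20)
        opd = build_opd(s, s.d_w_mm, n, spacing)
        x, y = pupil_coordinates(n, spacing)
        rho = np.hypot(x, y) / (s.d_w_mm / 2)
        theta = np.arctan2(y, x)
        mask = ~np.isnan(opd)
        modes = sorted(s.coeffs)
        fitted = zernike.fit_expansion(np.where(mask, opd, 0.0), rho, theta,
                                       modes, mask=mask)
        for nm in modes:
            assert fitted[nm] == pytest.approx(s.coeffs[nm], abs=1e-6)

    def test_linear_in_coefficients(self, rng):
        modes = [(2, -2), (3, 1), (4, 0)]
        a = {nm: float(v) for nm, v in zip(modes, rng.normal(0, 0.3, 3))}
        b = {nm: float(v) for nm, v in zip(modes, rng.normal(0, 0.3, 3))}
        both = {nm: a[nm] + b[nm] for nm in modes}
        mk = lambda c: build_opd(SubjectRecord("x", 0, 0, 5, 5, c), 5.0, 64, 0.09)
        oa, ob, oab = mk(a), mk(b), mk(both)
        m = ~np.isnan(oa)
        assert np.allclose(oab[m], oa[m] + ob[m], atol=1e-12)

    def test_extrapolation_beyond_fitted_zone_warns(self):
        s = SubjectRecord("x", 0, 0, 3.0, 4.0, {(2, 2): 0.1})
        with pytest.warns(PupilExtrapolationWarning):
            build_opd(s, 4.0, 64, 0.07)

    def test_invalid_pupil_rejected(self):
        s = SubjectRecord("x", 0, 0, 5.0, 5.0, {})
        with pytest.raises(ValueError):
            build_opd(s, -1.0, 64, 0.1)


class TestStilesCrawford:
    def test_published_one_over_e_radius(self):
        n, sp = 257, 0.05
        t = stiles_crawford_T(n, sp)
        c = n // 2
        assert t[c, c] == pytest.approx(1.0)
        r_idx = int(round(2.9 / sp))
        assert t[c, c + r_idx] == pytest.approx(np.exp(-1.0), rel=1e-3)
        profile = t[c, c:]
        assert np.all(np.diff(profile) < 0)


class TestPupilFunction:
    def test_unaberrated_reference_is_disc_indicator(self):
        s = SubjectRecord("x", 0, 0, 5.0, 5.0, {})
        opd = build_opd(s, 5.0, 128, 0.05)
        t = np.ones_like(opd)
        pf = pupil_function(opd, t, 555.0)
        inside = ~np.isnan(opd)
        assert np.allclose(pf.values[inside], 1.0)
        assert np.allclose(pf.values[~inside], 0.0)

    def test_phase_scales_inversely_with_wavelength(self):
        s = SubjectRecord("x", 0, 0, 5.0, 5.0, {(2, 2): 0.25})
        opd = build_opd(s, 5.0, 64, 0.09)
        t = np.ones_like(opd)
        lam = 740.0  # longest in-band wavelength: phase shrinks by 555/740
        p1 = pupil_function(opd, t, 555.0)
        p2 = pupil_function(opd, t, lam)
        inside = ~np.isnan(opd)
        ph1 = np.angle(p1.values[inside])
        ph2 = np.angle(p2.values[inside])
        scale = lam / 555.0
        assert np.allclose(np.exp(1j * ph1), np.exp(1j * scale * ph2), atol=1e-9)

    def test_wavelength_band_enforced(self):
        s = SubjectRecord("x", 0, 0, 5.0, 5.0, {})
        opd = build_opd(s, 5.0, 32, 0.2)
        with pytest.raises(ValueError):
            pupil_function(opd, np.ones_like(opd), 300.0)


def test_defocus_coefficient_diopter_roundtrip():
    for d_mm in (3.0, 5.0, 6.3):
        for D in (-1.2, 0.25, 0.8):
            c = defocus_coefficient(D, d_mm)
            assert diopters_from_coefficient(c, d_mm) == pytest.approx(D, abs=1e-12)
    # one hand-checked value: 0.25 D over a 6 mm pupil
    assert defocus_coefficient(0.25, 6.0) == pytest.approx(
        0.25 * 9.0 / (4 * np.sqrt(3)) / 0.555, rel=1e-12)
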