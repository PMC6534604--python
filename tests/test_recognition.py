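"""Template construction, normalized cross-correlation and guess sets."""

import numpy as np
import pytest

from acuitysim import recognition as R
from acuitysim.neural import build_ntf
from acuitysim.optotypes import LETTERS, render_letter
from acuitysim.psf import GridSpec, PSFImage, TransferFunction


def ncc_peak_oracle(image, template, background=1.0):
    """Brute-force peak of the lag-wise Pearson correlation between the
    template and the template-sized window of the zero-padded deviation
    image (independent loop implementation)."""
    img = background - np.asarray(image, float)
    tmpl = background - np.asarray(template, float)
    ih, iw = img.shape
    th, tw = tmpl.shape
    pad = np.zeros((ih + 2 * (th - 1), iw + 2 * (tw - 1)))
    pad[th - 1:th - 1 + ih, tw - 1:tw - 1 + iw] = img
    tm = tmpl.mean()
    tv = ((tmpl - tm) ** 2).sum()
    best = -np.inf
    for u in range(ih + th - 1):
        for v in range(iw + tw - 1):
            w = pad[u:u + th, v:v + tw]
            wv = ((w - w.mean()) ** 2).sum()
            if wv <= 1e-12 * th * tw:
                continue
            best = max(best, ((w - w.mean()) * (tmpl - tm)).sum() / np.sqrt(wv * tv))
    return best


@pytest.fixture(scope="module")
def delta_setup():
    """Identity optics on the fast grid: delta PSF and unity NTF."""
    g = GridSpec(n=256, dx_arcsec=5.724)
    vals = np.zeros((g.n, g.n))
    vals[g.n // 2, g.n // 2] = 1.0 / g.dx_deg ** 2
    psf = PSFImage(vals, g)
    ntf = TransferFunction(np.ones((g.n, g.n)), g)
    return g, psf, ntf


class TestPearsonPeak:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            img = rng.random((9, 8))
            tmpl = rng.random((6, 7))
            assert R.pearson_peak(img, tmpl) == pytest.approx(
                ncc_peak_oracle(img, tmpl), abs=1e-10)

    def test_identical_crops_give_unity(self, rng):
        x = rng.random((12, 12))
        assert R.pearson_peak(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_translation_invariance(self, rng):
        patch = rng.random((6, 6))
        a = np.ones((24, 24)); a[3:9, 2:8] = patch
        b = np.ones((24, 24)); b[11:17, 13:19] = patch
        assert R.pearson_peak(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_contrast_reversal_bounded_below(self, rng):
        x = rng.random((8, 8))
        neg = 2.0 - x  # deviation sign flipped about the unit background
        rho = R.pearson_peak(neg, x)
        assert -1.0 <= rho <= 1.0
        # zero-lag correlation of the reversal is exactly -1; the peak over
        # all lags can only be larger
        assert rho >= -1.0

    def test_constant_input_rejected(self):
        with pytest.raises(R.UndefinedCorrelationError):
            R.pearson_peak(np.ones((8, 8)), np.random.rand(8, 8))

    def test_matcher_consistent_with_reference_path(self, rng):
        # single-precision batched engine vs float64 reference
        tmpls = rng.random((4, 10, 10))
        stim = rng.random((10, 10))
        fast = R.rho_vector(1.0 - stim, 1.0 - tmpls)
        slow = [R.pearson_peak(stim, t) for t in tmpls]
        assert np.allclose(fast, slow, atol=2e-4)


class TestTemplates:
    def test_delta_psf_template_is_cropped_letter(self, delta_setup):
        g, psf, ntf = delta_setup
        ts = R.make_templates(psf, ntf, 0.0, g)
        assert ts.side < 200
        for k, ch in enumerate(ts.letters):
            ink = render_letter(ch, 0.0, g)
            r0, c0 = ts.origins[k]
            expected = ink.values[r0:r0 + ts.side, c0:c0 + ts.side]
            assert np.abs(ts.crops[k] - expected).max() < 1e-4

    def test_template_centroid_matches_ink_centroid(self, delta_setup):
        g, psf, ntf = delta_setup
        ts = R.make_templates(psf, ntf, 0.0, g)
        for k, ch in enumerate(ts.letters):
            dev = 1.0 - ts.crops[k]
            ri, ci = np.nonzero(dev > 0.5)
            img = render_letter(ch, 0.0, g)
            rr, cc = np.nonzero(img.ink)
            r0, c0 = img.origin
            assert abs((ri + ts.origins[k][0]).mean() - (rr + r0).mean()) < 1.0
            assert abs((ci + ts.origins[k][1]).mean() - (cc + c0).mean()) < 1.0

    def test_crop_side_strictly_below_200(self, delta_setup):
        g, psf, ntf = delta_setup
        for s in (0.3, 0.0, -0.35):
            assert R.make_templates(psf, ntf, s, g).side < 200


@pytest.fixture(scope="module")
def templates(delta_setup):
    g, psf, ntf = delta_setup
    return R.make_templates(psf, ntf, 0.0, g)


class TestRecognize:
    def test_zero_delta_rho_returns_argmax_only(self, templates):
        stim = templates.crop_of("E")
        res = R.recognize(stim, templates, 0.0, "E")
        assert res.guesses == ("E",)
        assert res.rho_max == pytest.approx(1.0, abs=1e-5)

    def test_noiseless_recognition_perfect_for_all_letters(self, templates):
        for ch in LETTERS:
            res = R.recognize(templates.crop_of(ch), templates, 0.0, ch)
            assert res.guesses == (ch,), ch

    def test_full_range_returns_whole_alphabet(self, templates):
        res = R.recognize(templates.crop_of("Q"), templates, 2.0, "Q")
        assert res.guesses == tuple(LETTERS)

    def test_guess_set_grows_with_delta_rho(self, templates):
        stim = templates.crop_of("C")
        prev = 0
        for dr in (0.0, 0.01, 0.05, 0.3, 2.0):
            res = R.recognize(stim, templates, dr, "C")
            assert len(res.guesses) >= prev
            assert "C" in res.guesses
            prev = len(res.guesses)

    def test_crop_is_speed_optimization_not_semantics(self, rng):
        # peak correlation from cropped windows equals the full-frame peak
        for _ in range(10):
            frame = np.ones((60, 60))
            patch = rng.random((8, 8))
            r, c = rng.integers(10, 40, 2)
            frame[r:r + 8, c:c + 8] = patch
            tmpl = rng.random((9, 9))
            full = R.pearson_peak(frame, tmpl)
            crop = frame[max(0, r - 6):r + 14, max(0, c - 6):c + 14]
            cropped = R.pearson_peak(crop, tmpl)
            assert cropped == pytest.approx(full, abs=1e-6)
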