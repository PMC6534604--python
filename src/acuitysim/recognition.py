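"""Template-matching character recognition.

Templates are the optically and neurally filtered — but noiseless —
images of all 26 letters at the tested size, cropped to the region that
actually carries letter information: a square window centered on the
centroid of the deviation-from-background image with half-side twice its
RMS radius (always below 200 pixels).  Similarity between the noisy
stimulus crop and each template is the peak of the normalized
cross-correlation surface over all integer lags (full correlation, linear
size = sum of the input sizes minus one), where each lag's value is
Pearson's correlation between the template and the template-sized window
of the zero-padded stimulus, both taken as deviations from the unit
background.  The peak ensures translation invariance.

The recognizer returns every template whose correlation lies within the
discrimination range [rho_max - delta_rho, rho_max]: near threshold a
subject cannot tell such candidates apart and starts guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .optotypes import LETTERS, render_letter
from .psf import DEFAULT_GRID, GridSpec, PSFImage, TransferFunction, apply_transfer, otf_from_psf

MAX_CROP_SIDE = 199  # strictly smaller than 200 x 200
_VAR_EPS = 1e-12


class TemplateError(ValueError):
    """Degenerate (all-background) template."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined for constant input."""


@dataclass(frozen=True)
class TemplateSet:
    """Filtered noiseless letter crops at one size, plus the crop geometry
    needed to cut the matching stimulus window."""

    size_logmar: float
    side: int
    letters: tuple[str, ...]
    crops: np.ndarray      # (26, side, side) filtered PI values
    origins: np.ndarray    # (26, 2) top-left (row, col) of each crop
    grid: GridSpec = DEFAULT_GRID

    def crop_of(self, letter: str) -> np.ndarray:
        return self.crops[self.letters.index(letter)]


@dataclass(frozen=True)
class RecognitionResult:
    """Per-template peak correlations and the discrimination-range guess set."""

    letter: str                  # displayed letter
    rho: dict[str, float]
    rho_max: float
    guesses: tuple[str, ...]     # alphabetical; always contains the argmax


def _moments(dev: np.ndarray) -> tuple[float, float, float]:
    """Centroid (row, col) and RMS radius of a non-negative weight map."""
    total = dev.sum(dtype=np.float64)
    if total <= 0:
        raise TemplateError("template image carries no letter deviation")
    r_idx, c_idx = np.indices(dev.shape)
    cr = float((dev * r_idx).sum() / total)
    cc = float((dev * c_idx).sum() / total)
    rms = float(np.sqrt((dev * ((r_idx - cr) ** 2 + (c_idx - cc) ** 2)).sum() / total))
    return cr, cc, rms


def _crop_window(center: tuple[float, float], half: int, n: int) -> tuple[int, int]:
    side = 2 * half + 1
    r0 = int(round(center[0])) - half
    c0 = int(round(center[1])) - half
    r0 = min(max(r0, 0), n - side)
    c0 = min(max(c0, 0), n - side)
    return r0, c0


def make_templates(psf: PSFImage, ntf: TransferFunction, s: float,
                   grid: GridSpec = DEFAULT_GRID,
                   combined_rhalf: np.ndarray | None = None) -> TemplateSet:
    """Build the filtered template set for letter size ``s`` (logMAR).

    Each letter is rendered, passed through the optical and neural filters,
    and cropped around the centroid of |1 - PI| with half-side equal to
    twice the RMS radius; within one size all letters share the common
    (largest, clipped) window side so correlation can be batched.
    """
    if combined_rhalf is None:
        combined_rhalf = (otf_from_psf(psf).rhalf * ntf.rhalf)
    work_dtype = np.float32 if combined_rhalf.dtype == np.complex64 else np.float64
    # the letter and its filter response live near the grid center; the
    # moment computation can ignore the far field (deviation mass there is
    # ~1e-6 of the total)
    mom_w = min(grid.n, 640)
    off = (grid.n - mom_w) // 2
    crops = []
    centers = []
    halves = []
    for ch in LETTERS:
        ii = render_letter(ch, s, grid).frame(work_dtype)
        pi = apply_transfer(ii, combined_rhalf)
        dev = np.abs(1.0 - pi[off:off + mom_w, off:off + mom_w])
        cr, cc, rms = _moments(dev)
        centers.append((cr + off, cc + off))
        halves.append(int(np.ceil(2.0 * rms)))
        crops.append(pi)
    half = min(max(halves), (MAX_CROP_SIDE - 1) // 2)
    side = 2 * half + 1
    out = np.empty((len(LETTERS), side, side))
    origins = np.empty((len(LETTERS), 2), dtype=int)
    for k, (pi, ctr) in enumerate(zip(crops, centers)):
        r0, c0 = _crop_window(ctr, half, grid.n)
        out[k] = pi[r0:r0 + side, c0:c0 + side]
        origins[k] = (r0, c0)
    return TemplateSet(float(s), side, LETTERS, out, origins, grid)


# ---------------------------------------------------------------------------
# normalized cross-correlation

def _ncc_surface(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Full normalized cross-correlation surface (a+b-1 per axis).

    ``image`` and ``template`` are deviation images (background 0).  Each
    element is the Pearson correlation between the template and the
    template-sized window of the zero-padded image at that lag; lags where
    the window is (numerically) constant are NaN.
    """
    ih, iw = image.shape
    th, tw = template.shape
    oh, ow = ih + th - 1, iw + tw - 1
    shape = [sfft.next_fast_len(oh), sfft.next_fast_len(ow)]
    f_img = sfft.rfft2(image, shape)
    f_img2 = sfft.rfft2(image * image, shape)
    f_tmpl = sfft.rfft2(template, shape)
    ones = np.ones((th, tw))
    f_ones = sfft.rfft2(ones, shape)

    n = th * tw
    t_mean = template.mean()
    t_ss = float(((template - t_mean) ** 2).sum())
    if t_ss <= _VAR_EPS:
        raise UndefinedCorrelationError("template is constant")

    # correlation <=> convolution with the flipped kernel; flipping is done
    # by conjugation in the frequency domain plus an index roll
    def corr(fa, fb):
        full = sfft.irfft2(fa * np.conj(fb), s=shape)
        return np.roll(full, (th - 1, tw - 1), axis=(0, 1))[:oh, :ow]

    s1 = corr(f_img, f_ones)        # sliding window sums of the image
    s2 = corr(f_img2, f_ones)
    num = corr(f_img, f_tmpl) - s1 * t_mean
    img_ss = s2 - s1 * s1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / np.sqrt(np.clip(img_ss, 0.0, None) * t_ss)
    rho[img_ss <= _VAR_EPS * n] = np.nan
    return np.clip(rho, -1.0, 1.0)


def pearson_peak(image_crop: np.ndarray, template_crop: np.ndarray,
                 background: float = 1.0) -> float:
    """Maximum of the normalized cross-correlation over all lags.

    Inputs are pipeline images with the given background level; they are
    converted to deviations internally.
    """
    img = background - np.asarray(image_crop, dtype=float)
    tmpl = background - np.asarray(template_crop, dtype=float)
    if float(((img - img.mean()) ** 2).sum()) <= _VAR_EPS:
        raise UndefinedCorrelationError("image crop is constant")
    surface = _ncc_surface(img, tmpl)
    peak = np.nanmax(surface)
    if np.isnan(peak):
        raise UndefinedCorrelationError("correlation undefined at every lag")
    return float(peak)


class TemplateMatcher:
    """Batched peak-correlation engine for one template stack.

    Precomputes the template FFTs and statistics once; `rho` then costs
    two FFTs of the stimulus plus one (batched) inverse FFT per template.
    Works in single precision: the ~1e-5 correlation error is far below
    the discrimination ranges of interest.  Because the transform size
    covers the full linear correlation, the circular result equals the
    linear one at every lag (zero-overlap lags carry zero window variance
    and are masked), so no recentering is needed before taking the peak.
    """

    def __init__(self, tmpl_devs: np.ndarray, stim_shape: tuple[int, int],
                 dtype=np.float32):
        tmpl_devs = np.asarray(tmpl_devs, dtype=dtype)
        self.dtype = dtype
        self.n_t, self.th, self.tw = tmpl_devs.shape
        ih, iw = stim_shape
        self.oh, self.ow = ih + self.th - 1, iw + self.tw - 1
        self.shape = [sfft.next_fast_len(self.oh), sfft.next_fast_len(self.ow)]
        self.f_tmpl = sfft.rfft2(tmpl_devs, self.shape, axes=(-2, -1)).conj()
        self.f_ones = sfft.rfft2(np.ones((self.th, self.tw), dtype=dtype),
                                 self.shape).conj()
        self.t_mean = tmpl_devs.mean(axis=(-2, -1), dtype=np.float64).astype(dtype)
        self.t_sd = np.sqrt(((tmpl_devs - self.t_mean[:, None, None]) ** 2)
                            .sum(axis=(-2, -1), dtype=np.float64)).astype(dtype)
        # variance floor: deviation images are O(1), so windows with a sum
        # of squares below eps*n are background-flat and carry no signal
        self._ss_floor = 1e-8 * self.th * self.tw

    def rho(self, stim_dev: np.ndarray) -> np.ndarray:
        """Peak NCC of one stimulus deviation crop against every template."""
        stim_dev = np.asarray(stim_dev, dtype=self.dtype)
        f_img = sfft.rfft2(stim_dev, self.shape)
        f_img2 = sfft.rfft2(stim_dev * stim_dev, self.shape)
        s1 = sfft.irfft2(f_img * self.f_ones, s=self.shape)
        s2 = sfft.irfft2(f_img2 * self.f_ones, s=self.shape)
        n = self.th * self.tw
        img_ss = s2 - s1 * s1 * self.dtype(1.0 / n)
        invalid = img_ss <= self._ss_floor
        img_sd = np.sqrt(np.clip(img_ss, 0.0, None))
        cross = sfft.irfft2(f_img[None] * self.f_tmpl, s=self.shape, axes=(-2, -1))
        out = np.empty(self.n_t, dtype=np.float64)
        for k in range(self.n_t):
            if self.t_sd[k] <= _VAR_EPS:
                out[k] = -np.inf
                continue
            num = cross[k] - s1 * self.t_mean[k]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = num / (img_sd * self.t_sd[k])
            r[invalid] = -np.inf
            out[k] = min(r.max(), 1.0)
        return out


def rho_vector(stim_dev: np.ndarray, tmpl_devs: np.ndarray) -> np.ndarray:
    """Peak correlation of one stimulus deviation crop against a stack of
    template deviation crops of identical shape."""
    return TemplateMatcher(tmpl_devs, stim_dev.shape).rho(stim_dev)


def recognize(ni_crop: np.ndarray, templates: TemplateSet,
              delta_rho: float, displayed: str,
              background: float = 1.0) -> RecognitionResult:
    """Identify the noisy stimulus crop against the full template set.

    Returns all letters whose peak correlation falls within
    [rho_max - delta_rho, rho_max]; with delta_rho = 0 this is the single
    best-correlated template.  Ties are resolved alphabetically by the
    ordering of the template set.
    """
    stim_dev = background - np.asarray(ni_crop, dtype=float)
    tmpl_devs = background - templates.crops
    rho = rho_vector(stim_dev, tmpl_devs)
    rho_max = float(rho.max())
    guesses = tuple(ch for ch, r in zip(templates.letters, rho)
                    if r >= rho_max - delta_rho)
    return RecognitionResult(displayed, dict(zip(templates.letters, map(float, rho))),
                             rho_max, guesses)
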