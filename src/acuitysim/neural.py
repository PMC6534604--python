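"""Neural transfer and cone-lattice noise.

The neural transfer function (NTF) is the ratio of the population contrast
sensitivity function to the mean optical transfer function of the
best-corrected eye, normalized to unit DC gain.  It acts as a fixed,
radially symmetric edge-enhancement filter: the optics of the individual
eye are already accounted for by the subject's own PSF, so the NTF is
built once from population models at a fixed reference pupil, not at the
subject's current pupil.

Neural noise is additive Gaussian white noise drawn per cone: one
independent deviate per cell of a hexagonal lattice with 120 cycles/degree
spatial frequency, added uniformly to every pixel of that cell.  The noise
standard deviation sigma is expressed relative to the unit background, so
it is a reciprocal signal-to-noise ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .psf import DEFAULT_GRID, GridSpec, TransferFunction

DEG_PER_RAD = 180.0 / np.pi


@dataclass(frozen=True)
class NeuralParams:
    """The two free neural parameters of the model."""

    sigma: float = 0.10       # additive noise SD relative to unit background
    delta_rho: float = 0.0025  # correlation discrimination range

    def __post_init__(self):
        if self.sigma < 0 or self.delta_rho < 0:
            raise ValueError("neural parameters must be non-negative")


# ---------------------------------------------------------------------------
# population CSF / mean optical MTF models

@dataclass(frozen=True)
class HyperbolicSecantCSF:
    """Difference-of-hyperbolic-secants contrast sensitivity function,

        S(f) = g * [sech((f/f0)^p) - a * sech(f/f1)],

    the band-pass form used for the foveal standard observer.  The gain g
    cancels in the NTF normalization; f0 and f1 set the high and
    low-frequency lobes (cycles/degree), a the low-frequency attenuation.
    """

    f0: float = 4.173
    f1: float = 1.362
    a: float = 0.8493
    p: float = 0.7786
    gain: float = 1.0

    def __call__(self, f_cpd: np.ndarray) -> np.ndarray:
        f = np.abs(np.asarray(f_cpd, dtype=float))
        sech = lambda x: 1.0 / np.cosh(x)
        return self.gain * (sech((f / self.f0) ** self.p) - self.a * sech(f / self.f1))


@dataclass(frozen=True)
class MeanOpticalMTF:
    """Mean radial optical MTF of the best-corrected human eye.

    Diffraction-limited MTF of the reference pupil multiplied by an
    exponential-plus-constant aberration factor,

        M(u) = D(u; d, 555) * [(1 - C) exp(-u / u1(d)) + C],
        u1(d) = 21.95 - 5.512 d + 0.3922 d^2   [cycles/degree],

    with a fixed photopic reference pupil diameter d (mm).  The residual
    high-frequency weight C is anchored so that the derived neural filter,
    applied on top of a nearly aberration-free eye, yields an acuity in
    the best-normal range (about -0.3 logMAR): C = 0.10 at the 4 mm
    reference pupil.
    """

    pupil_d_mm: float = 4.0
    lam_nm: float = 555.0
    C: float = 0.10

    @property
    def cutoff_cpd(self) -> float:
        return (self.pupil_d_mm * 1e-3) / (self.lam_nm * 1e-9) / DEG_PER_RAD

    def diffraction_limited(self, f_cpd: np.ndarray) -> np.ndarray:
        nu = np.clip(np.abs(np.asarray(f_cpd, dtype=float)) / self.cutoff_cpd, 0, 1)
        return (2.0 / np.pi) * (np.arccos(nu) - nu * np.sqrt(1.0 - nu ** 2))

    def __call__(self, f_cpd: np.ndarray) -> np.ndarray:
        d = self.pupil_d_mm
        u1 = 21.95 - 5.512 * d + 0.3922 * d * d
        f = np.abs(np.asarray(f_cpd, dtype=float))
        return self.diffraction_limited(f) * ((1.0 - self.C) * np.exp(-f / u1) + self.C)


def build_ntf(csf_model=None, motf_model=None,
              grid: GridSpec = DEFAULT_GRID, motf_floor: float = 1e-6) -> TransferFunction:
    """Neural transfer function NTF = CSF / MOTF on the frequency grid.

    The ratio is masked to zero beyond the MOTF cutoff (with a warning if
    the CSF is non-negligible there), passed through the DFT -> inverse-FFT
    numerical-consistency round trip, and normalized so that NTF(0) = 1.
    The resulting curve exceeds 1 over a mid-frequency band: an
    edge-enhancement filter.
    """
    csf_model = csf_model or HyperbolicSecantCSF()
    motf_model = motf_model or MeanOpticalMTF()
    fr = grid.freq_radius_cpd
    csf = csf_model(fr)
    motf = motf_model(fr)
    ok = motf > motf_floor
    ntf = np.zeros_like(csf)
    ntf[ok] = csf[ok] / motf[ok]
    if np.any(~ok & (csf > 1e-3 * csf.max())):
        warnings.warn("CSF extends beyond the MOTF cutoff; NTF masked to "
                      "zero there", stacklevel=2)
    # numerical-consistency round trip: express the filter through the same
    # discrete transform pair used for the OTF
    ntf = sfft.ifft2(sfft.fft2(ntf)).real
    ntf = ntf / ntf[0, 0]
    return TransferFunction(ntf, grid)


def apply_ntf(ri: np.ndarray, ntf: TransferFunction) -> np.ndarray:
    """Post-retinal neural image PI = FT[IFT[RI] * NTF].

    NTF(0) = 1 keeps the unit background of the filtered image."""
    return sfft.irfft2(sfft.rfft2(ri) * ntf.rhalf, s=ri.shape)


# ---------------------------------------------------------------------------
# hexagonal cone lattice

class ConeLattice:
    """Hexagonal cone lattice at 120 cycles/degree on the angular grid.

    Lattice basis: one axis horizontal, phase anchored at the image
    center.  ``assign`` maps pixels to the nearest lattice center and
    returns one integer id per pixel.
    """

    _ID_SPAN = 1 << 13

    def __init__(self, grid: GridSpec = DEFAULT_GRID, freq_cpd: float = 120.0):
        self.grid = grid
        self.freq_cpd = freq_cpd
        self.pitch_px = (1.0 / freq_cpd) / grid.dx_deg

    def assign(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Nearest-center cell ids for pixel index arrays (broadcastable)."""
        a = self.pitch_px
        h = a * np.sqrt(3.0) / 2.0
        c = self.grid.n // 2
        x = np.asarray(cols, dtype=float) - c
        y = np.asarray(rows, dtype=float) - c
        j0 = np.floor(y / h).astype(np.int64)
        best_d = None
        best_i = best_j = None
        for dj in (0, 1):
            j = j0 + dj
            i_est = x / a - j / 2.0
            i0 = np.floor(i_est).astype(np.int64)
            for di in (0, 1):
                i = i0 + di
                cx = (i + j / 2.0) * a
                cy = j * h
                d2 = (x - cx) ** 2 + (y - cy) ** 2
                if best_d is None:
                    best_d, best_i, best_j = d2, i, j
                else:
                    take = d2 < best_d
                    best_d = np.where(take, d2, best_d)
                    best_i = np.where(take, i, best_i)
                    best_j = np.where(take, j, best_j)
        return (best_i + self._ID_SPAN // 2) * self._ID_SPAN + (best_j + self._ID_SPAN // 2)

    def window_ids(self, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
        rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        return self.assign(rows, cols)


def cell_noise(ids: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """One zero-mean Gaussian deviate of SD sigma per distinct cell id,
    broadcast back to the pixel array (draw order follows sorted ids)."""
    uniq, inv = np.unique(ids, return_inverse=True)
    dev = rng.normal(0.0, sigma, size=uniq.size)
    return dev[inv].reshape(ids.shape)


def add_cone_noise(pi: np.ndarray, lattice: ConeLattice, sigma: float,
                   seed: int | np.random.Generator) -> np.ndarray:
    """Noisy image NI = PI + cone-lattice Gaussian white noise.

    Every pixel of a cell receives the same deviate; cells are
    independent.  Deterministic for a given seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return pi.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n0, n1 = pi.shape
    ids = lattice.window_ids(0, n0, 0, n1)
    return pi + cell_noise(ids, sigma, rng)
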