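"""Subject wavefronts: Zernike records, OPD maps and the pupil function.

The measured wavefront is a tenth-order OSA/ANSI Zernike expansion over the
aberrometer pupil of diameter ``d_w`` with coefficients in units of the
reference wavelength (555 nm).  Piston, the two tilts and — except for
explicitly myopic records — the defocus term are excluded upstream by the
aberrometer to remove instrument myopia.  The Zernike surface is treated as
a fixed physical surface: when the acuity-test pupil ``d_m`` differs from
``d_w`` the same polynomial expansion is evaluated over the new disc
(native extrapolation beyond the fitted zone triggers a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import zernike
from .eye import LAMBDA0_NM

#: 1/e amplitude radius of the Stiles-Crawford apodization, mm.
STILES_CRAWFORD_RADIUS_MM = 2.9


class PupilExtrapolationWarning(UserWarning):
    """Zernike surface evaluated beyond its fitted pupil zone."""


@dataclass(frozen=True)
class SubjectRecord:
    """One eye's wavefront measurement plus acuity-test conditions.

    Coefficients are keyed by (n, m) and expressed in units of the
    reference wavelength ``lambda0_nm``.  ``d_w_mm`` is the pupil diameter
    of the wavefront measurement, ``d_m_mm`` the (mean) pupil diameter
    during the acuity test.
    """

    id: str
    RE_D: float
    Cyl_D: float
    d_w_mm: float
    d_m_mm: float
    coeffs: dict[tuple[int, int], float] = field(default_factory=dict)
    lambda0_nm: float = LAMBDA0_NM

    def __post_init__(self):
        for d, tag in ((self.d_w_mm, "d_w"), (self.d_m_mm, "d_m")):
            if not 1.0 < d < 9.0:
                raise ValueError(f"{tag} = {d} mm outside the physiological 1..9 mm range")
        for (n, m), c in self.coeffs.items():
            zernike._check_nm(n, m)
            if n > zernike.MAX_ORDER:
                raise ValueError(f"order {n} beyond the tenth-order expansion")
            if n == 0 or n == 1:
                if c != 0.0:
                    raise ValueError("piston and tilt terms must be absent or zero")
            if abs(c) >= 10.0:
                raise ValueError(f"|Z_{n}^{m}| = {abs(c)} lambda0 is implausibly large")

    @property
    def coeffs_osa(self) -> dict[int, float]:
        """Coefficients keyed by the OSA/ANSI single index."""
        return {zernike.osa_index(n, m): c for (n, m), c in self.coeffs.items()}

    def higher_order_rms(self) -> float:
        """RMS (lambda0 units) of the order >= 3 part of the wavefront."""
        return float(np.sqrt(sum(c * c for (n, _), c in self.coeffs.items() if n >= 3)))

    def without_defocus(self) -> "SubjectRecord":
        coeffs = {nm: c for nm, c in self.coeffs.items() if nm != (2, 0)}
        return SubjectRecord(self.id, self.RE_D, self.Cyl_D, self.d_w_mm,
                             self.d_m_mm, coeffs, self.lambda0_nm)


def pupil_coordinates(n: int, spacing_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered pupil-plane coordinate grids X, Y in mm (FFT-center pixel
    convention: the origin sits at index n//2)."""
    ax = (np.arange(n) - n // 2) * spacing_mm
    return np.meshgrid(ax, ax)


def build_opd(subject: SubjectRecord, d_mm: float, n: int,
              spacing_mm: float) -> np.ndarray:
    """OPD map (lambda0 units) over the pupil disc of diameter ``d_mm``.

    The Zernike expansion stays normalized to the measurement radius
    ``d_w/2``; samples outside the active disc are NaN.
    """
    if d_mm <= 0:
        raise ValueError("pupil diameter must be positive")
    if d_mm > subject.d_w_mm * (1 + 1e-9):
        warnings.warn(
            f"pupil {d_mm} mm exceeds the fitted wavefront zone "
            f"({subject.d_w_mm} mm) for subject {subject.id}; Zernike "
            "polynomials extrapolated natively", PupilExtrapolationWarning,
            stacklevel=2)
    x, y = pupil_coordinates(n, spacing_mm)
    r = np.hypot(x, y)
    inside = r <= d_mm / 2.0
    rho = r / (subject.d_w_mm / 2.0)
    theta = np.arctan2(y, x)
    opd = zernike.evaluate_expansion(subject.coeffs, rho, theta)
    opd[~inside] = np.nan
    return opd


def stiles_crawford_T(n: int, spacing_mm: float,
                      radius_mm: float = STILES_CRAWFORD_RADIUS_MM) -> np.ndarray:
    """Gaussian amplitude apodization of the pupil, T(r) = exp(-(r/r_e)^2),
    modelling the directional sensitivity of cones; T equals 1/e at the
    published 2.9 mm radius."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    x, y = pupil_coordinates(n, spacing_mm)
    return np.exp(-(np.hypot(x, y) / radius_mm) ** 2)


def defocus_coefficient(defocus_D: float, pupil_d_mm: float,
                        lambda0_nm: float = LAMBDA0_NM) -> float:
    """Zernike defocus coefficient (lambda0 units, orthonormal Z_2^0 over
    the disc of diameter ``pupil_d_mm``) equivalent to a dioptric defocus.

    c_2^0 = D * (d/2)^2 / (4*sqrt(3)), converted from micrometres to
    lambda0 units.  Sign matches the aberrometer convention in which a
    myopic eye carries a negative Z_2^0.
    """
    a_mm = pupil_d_mm / 2.0
    c_um = defocus_D * a_mm ** 2 / (4.0 * np.sqrt(3.0))
    return c_um / (lambda0_nm * 1e-3)


def diopters_from_coefficient(c20_lam0: float, pupil_d_mm: float,
                              lambda0_nm: float = LAMBDA0_NM) -> float:
    """Inverse of :func:`defocus_coefficient`."""
    a_mm = pupil_d_mm / 2.0
    return c20_lam0 * (lambda0_nm * 1e-3) * 4.0 * np.sqrt(3.0) / a_mm ** 2


@dataclass(frozen=True)
class PupilFunction:
    """Generalized pupil function O = T * exp(-i 2 pi OPD) sampled on an
    N x N pupil-plane grid."""

    values: np.ndarray  # complex, zero outside the pupil disc
    spacing_mm: float
    diameter_mm: float
    wavelength_nm: float


def pupil_function(opd: np.ndarray, T: np.ndarray, lam_nm: float,
                   lambda0_nm: float = LAMBDA0_NM, *,
                   spacing_mm: float = 0.0, diameter_mm: float = 0.0,
                   extra_defocus: float = 0.0,
                   rho: np.ndarray | None = None) -> PupilFunction:
    """Complex pupil function at wavelength ``lam_nm``.

    ``opd`` is in lambda0 units (NaN outside the disc); the phase is
    -2*pi*OPD*(lambda0/lambda), following the convention that phase
    advances along propagation, so the PSF is the squared modulus of the
    *forward* Fourier transform of the returned array.  ``extra_defocus``
    is an additional Z_2^0 coefficient (lambda0 units over the active
    disc); it requires ``rho`` (radius normalized to the active disc).
    """
    if not 380.0 <= lam_nm <= 780.0:
        raise ValueError(f"wavelength {lam_nm} nm outside the visible band")
    total = np.array(opd, dtype=float)
    if extra_defocus != 0.0:
        if rho is None:
            raise ValueError("extra_defocus requires the normalized radius map")
        total = total + extra_defocus * zernike.zernike(2, 0, rho, np.zeros_like(rho))
    inside = ~np.isnan(total)
    phase = np.zeros_like(total)
    phase[inside] = -2.0 * np.pi * total[inside] * (lambda0_nm / lam_nm)
    values = np.zeros(total.shape, dtype=complex)
    values[inside] = T[inside] * np.exp(1j * phase[inside])
    return PupilFunction(values, spacing_mm, diameter_mm, lam_nm)
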