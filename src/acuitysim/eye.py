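"""Dispersion-enabled Gullstrand Exact schematic eye.

The Gullstrand Exact (No. I) unaccommodated eye — six spherical surfaces
with the crystalline lens split into cortex and high-index core — with its
fixed refractive indices replaced by Sellmeier-1 dispersion formulae fitted
to the Atchison-Smith ocular dispersion data.  The eye model is used
paraxially, for exactly two purposes: validating the geometry through the
effective focal length, and providing the longitudinal chromatic defocus
profile that drives the polychromatic point-spread computation.  All
monochromatic aberrations of an individual eye enter through the measured
wavefront instead, since letter size, pupil and wavefront are all given in
object space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

#: Reference wavelength of the wavefront measurement, nm.
LAMBDA0_NM = 555.0


class InvalidWavelengthError(ValueError):
    """Wavelength outside the visible band or at a Sellmeier pole."""


class DegenerateEyeError(ValueError):
    """Optical system with (near) zero power cannot form an image."""


@dataclass(frozen=True)
class OpticalMedium:
    """Ocular medium with Sellmeier-1 dispersion, n^2 - 1 = sum K_i l^2/(l^2 - L_i)."""

    name: str
    K: tuple[float, float, float]
    L: tuple[float, float, float]  # um^2

    def __post_init__(self):
        if not all(np.isfinite(self.K)) or not all(np.isfinite(self.L)):
            raise ValueError(f"non-finite Sellmeier coefficients for {self.name}")


def refractive_index(medium: OpticalMedium, lam_um: float | np.ndarray) -> float | np.ndarray:
    """Refractive index from the Sellmeier 1 formula.

    Parameters
    ----------
    lam_um : wavelength in vacuum, microns; must lie in the visible
        band 0.38..0.78 um and away from the Sellmeier poles.
    """
    lam_um = np.asarray(lam_um, dtype=float)
    if np.any(lam_um < 0.38) or np.any(lam_um > 0.78):
        raise InvalidWavelengthError(
            f"wavelength {lam_um} um outside the 0.38..0.78 um visible band")
    l2 = lam_um ** 2
    n2 = np.ones_like(l2)
    for k, pole in zip(medium.K, medium.L):
        denom = l2 - pole
        if np.any(np.abs(denom) < 1e-12):
            raise InvalidWavelengthError(
                f"wavelength at a Sellmeier pole of {medium.name}")
        n2 = n2 + k * l2 / denom
    n = np.sqrt(n2)
    return float(n) if n.ndim == 0 else n


# Sellmeier-1 coefficients of the ocular media (K dimensionless, L in um^2),
# fitted to the Atchison-Smith dispersion curves.  At 555 nm these reproduce
# the classical Gullstrand fixed indices (cornea 1.376, aqueous/vitreous
# 1.336, lens cortex 1.386, lens core 1.406) to < 1e-3.
CORNEA = OpticalMedium("cornea", (8.68e-1, 4.60e-4, 3.93e2), (9.35e-3, 1.41e-1, 4.41e4))
AQUEOUS = OpticalMedium("aqueous", (7.61e-1, 4.18e-4, 5.18e4), (1.01e-2, 1.42e-1, 5.73e6))
LENS_CORE = OpticalMedium("lens core", (9.42e-1, 1.29e-3, 4.71e4), (1.12e-2, 1.32e-1, 6.19e6))
LENS_CORTEX = OpticalMedium("lens cortex", (1.26e-3, 8.87e-1, 3.63), (1.31e-1, 1.15e-2, 4.88e2))
VITREOUS = OpticalMedium("vitreous", (7.61e-1, 2.73e-4, 4.30e4), (1.01e-2, 1.43e-1, 5.61e6))

MEDIA = {m.name: m for m in (CORNEA, AQUEOUS, LENS_CORE, LENS_CORTEX, VITREOUS)}


@dataclass(frozen=True)
class Surface:
    """Spherical refracting surface: radius of curvature and the axial
    distance to the next surface, both in mm; `medium` follows the surface."""

    radius_mm: float
    thickness_mm: float
    medium: OpticalMedium


@dataclass(frozen=True)
class SchematicEye:
    """Ordered refracting surfaces plus the vitreous depth to the retina.

    `retina_distance_mm` is the axial distance from the last lens surface
    to the retina; it is the adjustable quantity used to place the retina
    at the paraxial best focus of the reference wavelength.
    """

    surfaces: tuple[Surface, ...]
    retina_distance_mm: float
    stop_index: int = 3  # pupil: at the anterior lens surface

    def __post_init__(self):
        if len(self.surfaces) < 1:
            raise ValueError("eye needs at least one surface")
        if any(s.thickness_mm <= 0 for s in self.surfaces) or self.retina_distance_mm <= 0:
            raise ValueError("surface thicknesses must be positive")


# Gullstrand Exact (No. I) unaccommodated geometry (radii / thicknesses, mm).
# Total axial length 24.0 mm with the anatomical 16.80 mm vitreous depth.
_GULLSTRAND_SURFACES = (
    Surface(7.700, 0.500, CORNEA),
    Surface(6.800, 3.100, AQUEOUS),
    Surface(10.000, 0.546, LENS_CORTEX),
    Surface(7.911, 2.419, LENS_CORE),
    Surface(-5.760, 0.635, LENS_CORTEX),
    Surface(-6.000, 16.800, VITREOUS),
)


def gullstrand_exact(retina_distance_mm: float | None = None) -> SchematicEye:
    """The dispersion-enabled Gullstrand Exact eye.

    With the default ``retina_distance_mm=None`` the retina is placed at
    the 555 nm paraxial focus (the classical model is slightly hyperopic
    with the anatomical 24.0 mm length, so the focused eye is a cleaner
    chromatic reference).
    """
    eye = SchematicEye(_GULLSTRAND_SURFACES[:-1] + (_GULLSTRAND_SURFACES[-1],),
                       retina_distance_mm=16.800)
    if retina_distance_mm is None:
        return focus_retina(eye, LAMBDA0_NM)
    return replace(eye, retina_distance_mm=retina_distance_mm)


def _system_matrix(eye: SchematicEye, lam_nm: float, to_retina: bool):
    """Paraxial ray-transfer matrix acting on (y, n*u), lengths in mm,
    powers in mm^-1."""
    lam_um = lam_nm * 1e-3
    m = np.eye(2)
    n_before = 1.0
    for i, surf in enumerate(eye.surfaces):
        n_after = refractive_index(surf.medium, lam_um)
        power = (n_after - n_before) / surf.radius_mm  # mm^-1
        refr = np.array([[1.0, 0.0], [-power, 1.0]])
        t = surf.thickness_mm if i < len(eye.surfaces) - 1 else (
            eye.retina_distance_mm if to_retina else 0.0)
        trans = np.array([[1.0, t / n_after], [0.0, 1.0]])
        m = trans @ refr @ m
        n_before = n_after
    return m


def paraxial_trace(eye: SchematicEye, lam_nm: float) -> dict[str, float]:
    """Paraxial characterization of the eye at one wavelength.

    Returns
    -------
    dict with
      ``effective_focal_length_mm`` : object-space effective focal length
          (1/system power; the classical average value is 17.1 mm), and
      ``image_vergence_error_D`` : object-space vergence (diopters) of the
          point that images exactly onto the retina.  Zero for an
          emmetropic configuration; positive when the retina sits in front
          of the paraxial focus (hyperopic defocus).
    """
    m_sys = _system_matrix(eye, lam_nm, to_retina=False)
    power_mm = -m_sys[1, 0]
    if abs(power_mm) < 1e-9:
        raise DegenerateEyeError("schematic eye has zero paraxial power")
    efl_mm = 1.0 / power_mm

    m_ret = _system_matrix(eye, lam_nm, to_retina=True)
    a, b = m_ret[0, 0], m_ret[0, 1]
    if abs(b) < 1e-12:
        raise DegenerateEyeError("retina conjugate is degenerate")
    # a ray of height y from an axial object of vergence v (mm^-1) arrives
    # with reduced angle -v*y, so the retinal height is y*(a - b*v); the
    # retina-conjugate vergence zeroes it.
    v_mm = a / b
    return {"effective_focal_length_mm": float(efl_mm),
            "image_vergence_error_D": float(v_mm * 1e3)}


def focus_retina(eye: SchematicEye, lam_nm: float = LAMBDA0_NM) -> SchematicEye:
    """Move the retina to the paraxial focus at `lam_nm` (infinite object)."""
    m_sys = _system_matrix(eye, lam_nm, to_retina=False)
    a, c = m_sys[0, 0], m_sys[1, 0]
    if abs(c) < 1e-12:
        raise DegenerateEyeError("schematic eye has zero paraxial power")
    n_img = refractive_index(eye.surfaces[-1].medium, lam_nm * 1e-3)
    # parallel ray (y=1, w=0): y(t) = a + t/n * c*... propagate to y=0
    dist = -a / (c / n_img)
    return replace(eye, retina_distance_mm=float(dist))


@dataclass(frozen=True)
class ChromaticModel:
    """Discrete polychromatic description: wavelengths (nm), photopic
    weights (sum 1) and longitudinal chromatic defocus (D, relative to
    the 555 nm reference)."""

    wavelengths_nm: np.ndarray
    weights: np.ndarray
    defocus_D: np.ndarray

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("photopic weights must be non-negative")

    def to_dataframe(self):
        """Tabular view (wavelength_nm, weight, defocus_D), e.g. for CSV
        export."""
        import pandas as pd

        return pd.DataFrame({"wavelength_nm": self.wavelengths_nm,
                             "weight": self.weights,
                             "defocus_D": self.defocus_D})


def photopic_sensitivity(lam_nm: np.ndarray) -> np.ndarray:
    """CIE 1924 photopic luminosity V(lambda), Gaussian approximation
    1.019 exp(-285.4 (lambda_um - 0.5590)^2)."""
    lam_um = np.asarray(lam_nm, dtype=float) * 1e-3
    return 1.019 * np.exp(-285.4 * (lam_um - 0.5590) ** 2)


def chromatic_model(eye: SchematicEye | None = None,
                    lam_min_nm: float = 400.0, lam_max_nm: float = 700.0,
                    n_wavelengths: int = 24) -> ChromaticModel:
    """Photopically weighted chromatic defocus profile of the eye.

    24 wavelengths equally spaced over the visible band by default; the
    defocus at each wavelength is the object-space vergence error of the
    retina plane (retina fixed at the 555 nm focus), i.e. the longitudinal
    chromatic aberration expressed in diopters.
    """
    if n_wavelengths < 2:
        raise ValueError("chromatic model needs at least 2 wavelengths")
    if eye is None:
        eye = gullstrand_exact()
    lams = np.linspace(lam_min_nm, lam_max_nm, n_wavelengths)
    weights = photopic_sensitivity(lams)
    weights = weights / weights.sum()
    ref = paraxial_trace(eye, LAMBDA0_NM)["image_vergence_error_D"]
    defocus = np.array([paraxial_trace(eye, l)["image_vergence_error_D"] - ref
                        for l in lams])
    span = defocus.max() - defocus.min()
    if not 0.5 < span < 4.0:
        warnings.warn(f"chromatic defocus span {span:.2f} D outside the "
                      "expected human LCA range", stacklevel=2)
    return ChromaticModel(lams, weights, defocus)


def monochromatic_weighting(lam_nm: float = LAMBDA0_NM) -> ChromaticModel:
    """Degenerate single-wavelength model (used by the M2 ablation)."""
    return ChromaticModel(np.array([lam_nm]), np.array([1.0]), np.array([0.0]))
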