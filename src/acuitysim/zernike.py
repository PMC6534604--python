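"""Zernike polynomials on the unit disc.

OSA/ANSI and Noll sequential indexing, conversion between the two, and
evaluation of the orthonormal (RMS-normalized) polynomials up to radial
order 10, the order range produced by clinical Shack-Hartmann aberrometers.
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial

import numpy as np

#: Highest radial order supported (tenth-order expansion, 66 terms).
MAX_ORDER = 10
#: Highest OSA single index for a tenth-order expansion (n = m = 10).
MAX_OSA_INDEX = MAX_ORDER * (MAX_ORDER + 3) // 2  # = 65


def osa_index(n: int, m: int) -> int:
    """OSA/ANSI single index j for radial order n and azimuthal frequency m."""
    _check_nm(n, m)
    return (n * (n + 2) + m) // 2


def osa_to_nm(j: int) -> tuple[int, int]:
    """Inverse of :func:`osa_index`."""
    if not 0 <= j <= MAX_OSA_INDEX:
        raise IndexError(f"OSA index {j} outside 0..{MAX_OSA_INDEX}")
    n = int((np.sqrt(8 * j + 1) - 1) / 2)
    # guard against float rounding at triangular-number boundaries
    while n * (n + 1) // 2 > j:
        n -= 1
    while n * (n + 3) // 2 < j:
        n += 1
    m = 2 * j - n * (n + 2)
    if abs(m) > n or (n - m) % 2:
        raise IndexError(f"OSA index {j} does not map to a valid (n, m)")
    return n, m


@lru_cache(maxsize=1)
def _noll_table() -> tuple[dict[int, tuple[int, int]], dict[tuple[int, int], int]]:
    """Noll sequential ordering: n ascending, |m| ascending within n,
    sign chosen so that even j carries m >= 0 and odd j carries m < 0."""
    j_to_nm: dict[int, tuple[int, int]] = {}
    j = 1
    for n in range(MAX_ORDER + 1):
        for m_abs in range(n % 2, n + 1, 2):
            if m_abs == 0:
                j_to_nm[j] = (n, 0)
                j += 1
            else:
                pair = [j, j + 1]
                even = pair[0] if pair[0] % 2 == 0 else pair[1]
                odd = pair[0] if pair[0] % 2 == 1 else pair[1]
                j_to_nm[even] = (n, m_abs)
                j_to_nm[odd] = (n, -m_abs)
                j += 2
    nm_to_j = {nm: jj for jj, nm in j_to_nm.items()}
    return j_to_nm, nm_to_j


def noll_index(n: int, m: int) -> int:
    """Noll sequential index for (n, m)."""
    _check_nm(n, m)
    return _noll_table()[1][(n, m)]


def noll_to_nm(j: int) -> tuple[int, int]:
    table = _noll_table()[0]
    if j not in table:
        raise IndexError(f"Noll index {j} outside 1..{len(table)}")
    return table[j]


def osa_to_noll(j_osa: int) -> int:
    """Convert an OSA/ANSI single index to the Noll sequential index."""
    return noll_index(*osa_to_nm(j_osa))


def noll_to_osa(j_noll: int) -> int:
    """Convert a Noll sequential index to the OSA/ANSI single index."""
    return osa_index(*noll_to_nm(j_noll))


def _check_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - m) % 2:
        raise IndexError(f"invalid Zernike orders (n={n}, m={m})")


@lru_cache(maxsize=256)
def _radial_coeffs(n: int, m_abs: int) -> tuple[float, ...]:
    """Polynomial coefficients of R_n^|m| in rho, highest power first."""
    coeffs = np.zeros(n + 1)
    for k in range((n - m_abs) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k)
                * factorial((n + m_abs) // 2 - k)
                * factorial((n - m_abs) // 2 - k)))
        coeffs[n - (n - 2 * k)] += c  # position for power n-2k
    return tuple(coeffs)


def radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^|m|(rho).

    Evaluated natively for any rho >= 0; callers that pass rho > 1
    (pupil larger than the fitted wavefront) get the polynomial's
    analytic continuation.
    """
    _check_nm(n, m)
    return np.polyval(_radial_coeffs(n, abs(m)), np.asarray(rho, dtype=float))


def zernike(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Orthonormal Zernike polynomial Z_n^m (OSA/ANSI normalization).

    The normalization makes the RMS of each mode over the unit disc equal
    to 1, so a coefficient value is directly the RMS wavefront error
    contributed by that mode.
    """
    _check_nm(n, m)
    norm = np.sqrt(2.0 * (n + 1)) if m != 0 else np.sqrt(n + 1.0)
    r = radial_poly(n, m, rho)
    if m > 0:
        return norm * r * np.cos(m * theta)
    if m < 0:
        return norm * r * np.sin(-m * theta)
    return norm * r


def evaluate_expansion(coeffs: dict[tuple[int, int], float],
                       rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Sum of coefficient-weighted orthonormal Zernike modes."""
    out = np.zeros(np.broadcast(rho, theta).shape)
    for (n, m), c in coeffs.items():
        if c != 0.0:
            out += c * zernike(n, m, rho, theta)
    return out


def fit_expansion(opd: np.ndarray, rho: np.ndarray, theta: np.ndarray,
                  modes: list[tuple[int, int]],
                  mask: np.ndarray | None = None) -> dict[tuple[int, int], float]:
    """Least-squares Zernike fit of a sampled map over the unit disc."""
    if mask is None:
        mask = rho <= 1.0
    cols = [zernike(n, m, rho[mask], theta[mask]) for n, m in modes]
    a = np.column_stack(cols)
    sol, *_ = np.linalg.lstsq(a, opd[mask], rcond=None)
    return {nm: float(v) for nm, v in zip(modes, sol)}
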