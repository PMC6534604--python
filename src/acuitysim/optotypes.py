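"""Binary optotype rendering: the 26-letter extended Sloan character set.

Sloan optotypes live on a 5 x 5 design grid: letter height and width are
five stroke widths.  Letter size is expressed in logMAR, the decimal
logarithm of the stroke width in arcmin.  Glyphs are built-in vector
outlines — annuli and circular arcs for the canonical curved letters,
rectangles and buffered diagonal strokes for the rest — rasterized with
4x4 supersampling and a 0.5 coverage threshold onto the standard
1024-pixel angular grid (background 1, strokes 0, letter centered).

The ten canonical Sloan letters (C D H K N O R S V Z) follow the
published construction; the remaining sixteen use the same 5 x 5,
one-stroke-width design rules.  `GLYPH_SOURCES` allows substituting an
external glyph table for exact font replication.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from .psf import DEFAULT_GRID, FieldImage, GridSpec

LETTERS = tuple(string.ascii_uppercase)

ARCMIN_PER_PIXEL = DEFAULT_GRID.dx_arcsec / 60.0  # 0.0954 arcmin


class LetterSizeError(ValueError):
    """Letter too large for the image grid."""


class GlyphError(KeyError):
    """No outline defined for the requested character."""


def _ring(cx, cy, r_out, r_in):
    return Point(cx, cy).buffer(r_out, quad_segs=64).difference(
        Point(cx, cy).buffer(r_in, quad_segs=64))


def _ellipse_ring(cx, cy, rx_out, ry_out, rx_in, ry_in):
    """Difference of two concentric axis-aligned ellipses (unit-stroke
    bowls: out minus in radii equal the stroke width on each axis)."""
    outer = affinity.scale(Point(0, 0).buffer(1.0, quad_segs=64),
                           rx_out, ry_out, origin=(0.0, 0.0))
    inner = affinity.scale(Point(0, 0).buffer(1.0, quad_segs=64),
                           rx_in, ry_in, origin=(0.0, 0.0))
    return affinity.translate(outer.difference(inner), cx, cy)


def _bowl(cx, cy, rx_out, ry_out):
    """Right-opening half-ellipse ring of stroke width 1."""
    ring = _ellipse_ring(cx, cy, rx_out, ry_out, rx_out - 1.0, ry_out - 1.0)
    return ring.intersection(box(cx, cy - ry_out, cx + rx_out, cy + ry_out))


def _stroke(p0, p1, w=1.0):
    """Straight stroke of width w with flat end caps."""
    return LineString([p0, p1]).buffer(w / 2.0, cap_style="flat", quad_segs=8)


def _rects(*spans):
    return unary_union([box(x0, y0, x1, y1) for x0, y0, x1, y1 in spans])


def _build_glyphs() -> dict[str, shapely.Geometry]:
    """Vector outlines on the 5 x 5 design grid (x right, y up)."""
    g: dict[str, shapely.Geometry] = {}
    ring = _ring(2.5, 2.5, 2.5, 1.5)

    # --- canonical Sloan letters -----------------------------------------
    g["C"] = ring.difference(box(2.5, 2.0, 5.0, 3.0))
    g["D"] = unary_union([
        _rects((0, 0, 1, 5), (1, 4, 2.5, 5), (1, 0, 2.5, 1)),
        ring.intersection(box(2.5, 0, 5, 5)),
    ])
    g["H"] = _rects((0, 0, 1, 5), (4, 0, 5, 5), (1, 2, 4, 3))
    g["K"] = unary_union([
        _rects((0, 0, 1, 5)),
        _stroke((1.0, 2.5), (4.8, 5.0)),
        _stroke((1.0, 2.5), (4.8, 0.0)),
    ])
    g["N"] = unary_union([
        _rects((0, 0, 1, 5), (4, 0, 5, 5)),
        _stroke((0.5, 5.0), (4.5, 0.0)),
    ])
    g["O"] = ring
    g["R"] = unary_union([
        _rects((0, 0, 1, 5), (0, 4, 1.5, 5), (0, 2, 1.5, 3)),
        _bowl(1.0, 3.5, 3.5, 1.5),
        _stroke((2.8, 2.0), (4.5, 0.0)),
    ])
    # S: two stacked elliptical arcs (5 wide, 2.5 tall each), the upper one
    # open at the lower right, the lower one open at the upper left
    _s_ring = affinity.scale(_ring(0.0, 0.0, 1.25, 0.25), xfact=2.0, yfact=1.0,
                             origin=(0.0, 0.0))
    g["S"] = unary_union([
        affinity.translate(_s_ring, 2.5, 3.75).difference(box(2.5, 2.5, 5.0, 3.75)),
        affinity.translate(_s_ring, 2.5, 1.25).difference(box(0.0, 1.25, 2.5, 2.5)),
    ])
    g["V"] = unary_union([
        _stroke((0.5, 5.0), (2.5, 0.0)),
        _stroke((4.5, 5.0), (2.5, 0.0)),
    ])
    g["Z"] = unary_union([
        _rects((0, 4, 5, 5), (0, 0, 5, 1)),
        _stroke((4.5, 4.0), (0.5, 1.0)),
    ])

    # --- extension to the full alphabet, same design rules ----------------
    g["A"] = unary_union([
        _stroke((2.5, 5.0), (0.5, 0.0)),
        _stroke((2.5, 5.0), (4.5, 0.0)),
        _rects((1.0, 1.0, 4.0, 2.0)),
    ])
    g["B"] = unary_union([
        _rects((0, 0, 1, 5), (0, 4, 1.5, 5), (0, 2, 1.5, 3), (0, 0, 1.5, 1)),
        _bowl(1.0, 3.75, 3.3, 1.25),
        _bowl(1.0, 1.25, 3.6, 1.25),
    ])
    g["E"] = _rects((0, 0, 1, 5), (0, 4, 5, 5), (0, 2, 4, 3), (0, 0, 5, 1))
    g["F"] = _rects((0, 0, 1, 5), (0, 4, 5, 5), (0, 2, 4, 3))
    g["G"] = unary_union([
        ring.difference(box(2.5, 3.0, 5.0, 4.0)),
        _rects((2.8, 2.0, 4.6, 3.0)),
    ])
    g["I"] = _rects((2, 0, 3, 5))
    g["J"] = unary_union([
        _rects((3.5, 1.0, 4.5, 5.0)),
        _ring(2.5, 2.0, 2.0, 1.0).intersection(box(0, 0, 5, 2.0)),
    ])
    g["L"] = _rects((0, 0, 1, 5), (0, 0, 5, 1))
    g["M"] = unary_union([
        _rects((0, 0, 1, 5), (4, 0, 5, 5)),
        _stroke((0.5, 5.0), (2.5, 1.5)),
        _stroke((4.5, 5.0), (2.5, 1.5)),
    ])
    g["P"] = unary_union([
        _rects((0, 0, 1, 5), (0, 4, 1.5, 5), (0, 2, 1.5, 3)),
        _bowl(1.0, 3.5, 3.5, 1.5),
    ])
    g["Q"] = unary_union([ring, _stroke((2.9, 2.1), (4.9, 0.1))])
    g["T"] = _rects((0, 4, 5, 5), (2, 0, 3, 5))
    g["U"] = unary_union([
        _rects((0, 2.5, 1, 5), (4, 2.5, 5, 5)),
        ring.intersection(box(0, 0, 5, 2.5)),
    ])
    g["W"] = unary_union([
        _stroke((0.5, 5.0), (1.6, 0.0)),
        _stroke((1.6, 0.0), (2.5, 3.2)),
        _stroke((2.5, 3.2), (3.4, 0.0)),
        _stroke((3.4, 0.0), (4.5, 5.0)),
    ])
    g["X"] = unary_union([
        _stroke((0.5, 5.0), (4.5, 0.0)),
        _stroke((4.5, 5.0), (0.5, 0.0)),
    ])
    g["Y"] = unary_union([
        _stroke((0.5, 5.0), (2.5, 2.5)),
        _stroke((4.5, 5.0), (2.5, 2.5)),
        _rects((2, 0, 3, 3)),
    ])

    frame = box(0.0, 0.0, 5.0, 5.0)
    out = {}
    for k, v in g.items():
        clipped = v.intersection(frame)
        shapely.prepare(clipped)
        out[k] = clipped
    return out


@lru_cache(maxsize=1)
def _glyphs() -> dict[str, shapely.Geometry]:
    return _build_glyphs()


#: Named glyph sources; "builtin" is the vector set above.  External
#: sources can be registered as letter -> shapely geometry mappings.
GLYPH_SOURCES: dict[str, object] = {"builtin": None}


@dataclass(frozen=True)
class LetterImage:
    """Binary ideal image (II): background 1, strokes 0, letter centered."""

    letter: str
    size_logmar: float
    ink: np.ndarray          # bool patch, True on strokes
    origin: tuple[int, int]  # top-left (row, col) of the patch in the frame
    grid: GridSpec = DEFAULT_GRID

    def frame(self, dtype=np.float64) -> np.ndarray:
        """Full-frame II matrix (background 1, strokes 0)."""
        out = np.ones((self.grid.n, self.grid.n), dtype=dtype)
        r0, c0 = self.origin
        h, w = self.ink.shape
        out[r0:r0 + h, c0:c0 + w] = np.where(self.ink, dtype(0.0), dtype(1.0))
        return out

    @property
    def values(self) -> np.ndarray:
        return self.frame()

    def as_field(self) -> FieldImage:
        return FieldImage(self.values, "II", self.size_logmar, self.grid)

    @property
    def ink_area_px(self) -> int:
        return int(self.ink.sum())


def stroke_width_pixels(s: float, grid: GridSpec = DEFAULT_GRID) -> float:
    """Stroke width in pixels for letter size s (logMAR).

    The stroke subtends 10**s arcmin; at 5.724 arcsec/pixel, s = 0 gives
    10.483 pixels.
    """
    if not -0.5 <= s <= 0.5:
        raise LetterSizeError(f"letter size {s} logMAR outside the supported range")
    w = 10.0 ** s * 60.0 / grid.dx_arcsec
    if 5.0 * w > grid.n:
        raise LetterSizeError(f"letter at {s} logMAR does not fit the grid")
    return w


@lru_cache(maxsize=512)
def _render_cached(letter: str, s_key: float, n: int, dx: float,
                   supersample: int) -> tuple[np.ndarray, tuple[int, int]]:
    grid = GridSpec(n, dx)
    w = stroke_width_pixels(s_key, grid)
    glyphs = _glyphs()
    if letter not in glyphs:
        raise GlyphError(f"no glyph outline for {letter!r}")
    geom = glyphs[letter]
    c = n // 2  # letter center pixel
    half = 2.5 * w
    lo = int(np.floor(c - half)) - 1
    hi = int(np.ceil(c + half)) + 1
    npix = hi - lo + 1
    ss = supersample
    # subpixel sample centers in frame-pixel units
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    px = np.arange(lo, hi + 1)
    pos = (px[:, None] + sub[None, :]).ravel()
    gx = (pos - c) / w + 2.5          # glyph x: right
    gy = (c - pos) / w + 2.5          # glyph y: up, image rows run down
    xg, yg = np.meshgrid(gx, gy)
    inside = shapely.contains_xy(geom, xg, yg)
    cov = inside.reshape(npix, ss, npix, ss).mean(axis=(1, 3))
    ink = cov >= 0.5
    return ink, (lo, lo)


def render_letter(letter: str, s: float, grid: GridSpec = DEFAULT_GRID,
                  glyph_source: str = "builtin",
                  supersample: int = 4) -> LetterImage:
    """Rasterize one letter at size ``s`` (logMAR) onto the standard grid.

    Deterministic; the glyph outline is scaled so the stroke width equals
    10**s arcmin, supersampled ``supersample`` x per axis and thresholded
    at 0.5 coverage.
    """
    letter = letter.upper()
    if glyph_source != "builtin":
        raise GlyphError(f"unknown glyph source {glyph_source!r}")
    ink, origin = _render_cached(letter, round(float(s), 6), grid.n,
                                 grid.dx_arcsec, supersample)
    return LetterImage(letter, float(s), ink, origin, grid)


def render_alphabet(s: float, grid: GridSpec = DEFAULT_GRID) -> list[LetterImage]:
    return [render_letter(ch, s, grid) for ch in LETTERS]
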