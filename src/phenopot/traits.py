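"""The 15 static traits of one plant at one time point.

Geometric descriptors (areas in cm², lengths in cm, computed in pixels and
converted once at output):

* PA / PP — projected area and perimeter of the plant mask,
* CA / CP — area and perimeter of its convex hull,
* AXL / AXS — long and short side of the minimum-area oriented bounding box,
* PAR — PA over the circumscribed (pot-circle) area,
* CAR — PA over CA.

Color descriptors, averaged over mask pixels: mean R, G, B; mean H, S, V on
a [0, 255] scale (H in degrees × 255/360); and the excess-green index
ExG = 2g − r − b on chromatic coordinates (black pixels contribute 0).

Conventions pinned here: the hull and OBB are computed on pixel *corner*
points (pixels as unit squares), so an axis-aligned w×h rectangle of pixels
measures exactly w×h and CA ≥ PA holds identically; PP uses the Crofton
perimeter estimator with holes filled, which is accurate to a few tenths of
a percent on smooth outlines where boundary-trace chain codes overestimate
by ~5%.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

import numpy as np
from scipy.ndimage import binary_fill_holes
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint
from skimage.color import rgb2hsv
from skimage.measure import perimeter_crofton

from .segmentation import PlantMask

__all__ = ["StaticTraits", "TRAIT_NAMES", "geometric_traits", "color_traits",
           "extract_traits"]

TRAIT_NAMES = ("PA", "PP", "CA", "CP", "AXL", "AXS", "PAR", "CAR",
               "R", "G", "B", "H", "S", "V", "ExG")


@dataclass
class StaticTraits:
    PA: float
    PP: float
    CA: float
    CP: float
    AXL: float
    AXS: float
    PAR: float
    CAR: float
    R: float
    G: float
    B: float
    H: float
    S: float
    V: float
    ExG: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _corner_hull(mask: np.ndarray) -> np.ndarray:
    """Convex hull vertices (x, y) of mask pixels treated as unit squares."""
    pts = np.argwhere(mask)[:, ::-1].astype(float)   # (x, y)
    if len(pts) >= 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: keep all, corners still span the shape
    offsets = np.array([[-0.5, -0.5], [0.5, -0.5], [-0.5, 0.5], [0.5, 0.5]])
    corners = (pts[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def geometric_traits(mask: PlantMask | np.ndarray, mm_per_px: float,
                     circle: tuple[float, float, float] | None = None
                     ) -> dict[str, float]:
    """PA, PP, CA, CP, AXL, AXS, PAR, CAR for one plant mask.

    ``circle`` (cx, cy, r in px) defines the circumscribed pot region for
    PAR; without it PAR is reported as NaN.  Raises on an empty mask.
    """
    if isinstance(mask, PlantMask):
        circle = circle if circle is not None else mask.circle
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("no plant: empty mask")
    cm = mm_per_px / 10.0

    pa = n_px * cm**2
    pp = perimeter_crofton(binary_fill_holes(mask), directions=4) * cm

    hull = _corner_hull(mask)
    x, y = hull[:, 0], hull[:, 1]
    ca = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    d = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    cp = float(np.hypot(d[:, 0], d[:, 1]).sum())

    rect = MultiPoint([tuple(p) for p in hull]).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)[:-1]
    sides = np.hypot(*(np.diff(coords, axis=0, append=coords[:1]).T))
    axl, axs = float(np.max(sides[:2])), float(np.min(sides[:2]))

    par = np.nan
    if circle is not None:
        par = n_px / (np.pi * circle[2] ** 2)
    return {
        "PA": pa, "PP": pp,
        "CA": ca * cm**2, "CP": cp * cm,
        "AXL": axl * cm, "AXS": axs * cm,
        "PAR": par, "CAR": pa / (ca * cm**2),
    }


def color_traits(crop: np.ndarray, mask: PlantMask | np.ndarray
                 ) -> dict[str, float]:
    """Mean R, G, B, H, S, V (each on [0, 255]) and ExG over mask pixels."""
    if isinstance(mask, PlantMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no plant: empty mask")
    rgb = np.asarray(crop, dtype=float)
    px = rgb[mask]
    r_m, g_m, b_m = px.mean(axis=0)

    hsv = rgb2hsv(np.asarray(crop, dtype=np.uint8))[mask] * 255.0
    h_m, s_m, v_m = hsv.mean(axis=0)

    tot = px.sum(axis=1)
    chrom = np.divide(px, tot[:, None], out=np.zeros_like(px),
                      where=tot[:, None] > 0)
    exg = float(np.mean(2 * chrom[:, 1] - chrom[:, 0] - chrom[:, 2]))
    return {"R": float(r_m), "G": float(g_m), "B": float(b_m),
            "H": float(h_m), "S": float(s_m), "V": float(v_m), "ExG": exg}


def extract_traits(crop: np.ndarray, mask: PlantMask | np.ndarray,
                   mm_per_px: float,
                   circle: tuple[float, float, float] | None = None
                   ) -> StaticTraits:
    """All 15 static traits for one (crop, mask, pot circle, scale) tuple."""
    geo = geometric_traits(mask, mm_per_px, circle)
    col = color_traits(crop, mask)
    return StaticTraits(**geo, **col)
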