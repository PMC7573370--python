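"""Brute-force reference implementations of the static-trait definitions.

The synthetic scene generator uses these routines to attach ground-truth
trait values to every rasterized plant mask.  They follow the same trait
definitions as :mod:`phenopot.traits` but through deliberately independent
algorithms (hand-written monotone-chain hull, rotating calipers, direct
pixel enumeration, analytic rosette geometry) so that the measurement path
can be validated against them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "convex_hull",
    "polygon_area",
    "polygon_perimeter",
    "min_area_rect_sides",
    "pixel_corner_points",
    "mask_geometry",
    "rosette_area_mm2",
    "rosette_arc_length_mm",
    "hsv_means",
]


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull of 2-D points via Andrew's monotone chain.

    Returns hull vertices in counter-clockwise order.  Written from first
    principles (no scipy) so it can serve as an oracle for the hull used by
    the trait-measurement path.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) <= 2:
        return pts
    # lexicographic sort by (x, y)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.array(lower[:-1] + upper[:-1])


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    if len(v) < 2:
        return 0.0
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def min_area_rect_sides(points: np.ndarray) -> tuple[float, float]:
    """(long, short) side of the minimum-area oriented bounding box.

    Exhaustive rotating calipers: tries every hull edge direction and keeps
    the axis-aligned bounding box of the rotated hull with minimal area.
    """
    hull = convex_hull(points)
    if len(hull) == 1:
        return 0.0, 0.0
    if len(hull) == 2:
        return float(np.hypot(*(hull[1] - hull[0]))), 0.0
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.arctan2(edges[:, 1], edges[:, 0])
    best = None
    for th in angles:
        c, s = np.cos(-th), np.sin(-th)
        rot = hull @ np.array([[c, -s], [s, c]]).T
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        if best is None or w * h < best[0]:
            best = (w * h, max(w, h), min(w, h))
    assert best is not None
    return best[1], best[2]


def pixel_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner points (x, y) of all foreground pixels treated as unit squares."""
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)
    offsets = np.array([[-0.5, -0.5], [0.5, -0.5], [-0.5, 0.5], [0.5, 0.5]])
    return (pts[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


def mask_geometry(mask: np.ndarray, mm_per_px: float,
                  pot_radius_px: float | None = None) -> dict[str, float]:
    """Geometric traits of a binary mask by direct pixel enumeration.

    Areas in cm², lengths in cm; PAR/CAR unitless.  PP is omitted here
    (the generator attaches the analytic boundary length instead).
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty mask")
    cm_per_px = mm_per_px / 10.0
    pa = n_px * cm_per_px**2
    corners = pixel_corner_points(mask)
    hull = convex_hull(corners)
    ca = polygon_area(hull) * cm_per_px**2
    cp = polygon_perimeter(hull) * cm_per_px
    axl, axs = min_area_rect_sides(hull)
    out = {
        "PA": pa,
        "CA": ca,
        "CP": cp,
        "AXL": axl * cm_per_px,
        "AXS": axs * cm_per_px,
        "CAR": pa / ca if ca > 0 else np.nan,
    }
    if pot_radius_px is not None:
        cca = np.pi * pot_radius_px**2 * cm_per_px**2
        out["PAR"] = pa / cca
    else:
        out["PAR"] = np.nan
    return out


def rosette_area_mm2(radius_mm: float, lobe_amplitude: float) -> float:
    """Exact area of the polar rosette r(θ) = R·(1 + a·cos kθ).

    ½∫r² dθ = πR²(1 + a²/2), independent of the lobe count.
    """
    return np.pi * radius_mm**2 * (1.0 + lobe_amplitude**2 / 2.0)


def rosette_arc_length_mm(radius_mm: float, lobe_amplitude: float,
                          lobe_count: int, n: int = 20000) -> float:
    """Arc length of r(θ) = R·(1 + a·cos kθ) by dense numerical quadrature."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = radius_mm * (1.0 + lobe_amplitude * np.cos(lobe_count * theta))
    dr = -radius_mm * lobe_amplitude * lobe_count * np.sin(lobe_count * theta)
    return float(np.sqrt(r**2 + dr**2).sum() * (2.0 * np.pi / n))


def hsv_means(rgb: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Mean H, S, V on the [0, 255] scale over mask pixels.

    Hexcone conversion written out explicitly (independent of skimage):
    H in degrees rescaled by 255/360, S and V rescaled from [0,1] to [0,255].
    Achromatic pixels get H = 0.
    """
    px = np.asarray(rgb, dtype=float)[np.asarray(mask, dtype=bool)] / 255.0
    r, g, b = px[:, 0], px[:, 1], px[:, 2]
    v = np.max(px, axis=1)
    mn = np.min(px, axis=1)
    c = v - mn
    h = np.zeros_like(v)
    nz = c > 0
    rmax = nz & (v == r)
    gmax = nz & (v == g) & ~rmax
    bmax = nz & ~rmax & ~gmax
    h[rmax] = ((g[rmax] - b[rmax]) / c[rmax]) % 6.0
    h[gmax] = (b[gmax] - r[gmax]) / c[gmax] + 2.0
    h[bmax] = (r[bmax] - g[bmax]) / c[bmax] + 4.0
    h *= 60.0  # degrees
    s = np.where(v > 0, c / np.maximum(v, 1e-12), 0.0)
    return (
        float(np.mean(h * 255.0 / 360.0)),
        float(np.mean(s * 255.0)),
        float(np.mean(v * 255.0)),
    )
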