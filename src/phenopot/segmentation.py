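"""Plant segmentation inside a pot crop, with a vegetation-index baseline.

A segmentation backend is any callable mapping an RGB crop to a per-pixel
plant-probability map in [0, 1].  The bundled baseline rescales a
vegetation index — excess green 2g−r−b for green foliage, or its purple
counterpart 2(r+b)/2−... (excess purple r+b−2g) for anthocyanin-rich
varieties — into [0, 1] by robust percentile normalization.

Post-processing follows the standard recipe: fixed-threshold binarization,
largest connected component, and restriction to the pot circle (the
phenotyping region).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.measure import label

__all__ = [
    "PlantMask",
    "VegetationIndexBackend",
    "segment_plant",
    "binarize_and_select",
    "dice",
]


@dataclass
class PlantMask:
    """Binary plant mask on the crop grid, restricted to the pot circle."""

    mask: np.ndarray                               # bool, H×W
    circle: tuple[float, float, float] | None      # (cx, cy, r) px
    n_components: int                              # before selection

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


class VegetationIndexBackend:
    """Soft plant map from a chromatic vegetation index.

    ``index='green'`` uses excess green 2g−r−b; ``index='purple'`` uses
    excess purple r+b−2g; ``index='auto'`` picks whichever of the two puts
    the smaller pixel fraction in its upper half (the plant is the minority
    class of a pot crop).  The index is rescaled to [0, 1] between its 1st
    percentile and the median of its candidate plant pixels (selected by
    value, not count, because the plant may cover well under 1% of the crop
    early on).  Typical plant pixels therefore map near 1 and the fixed 0.5
    binarization threshold sits midway between background and foliage
    levels.  Crops with no index contrast (range below ``min_contrast``)
    yield an all-zero map, so a uniform background produces an empty mask
    downstream.
    """

    def __init__(self, index: str = "green", min_contrast: float = 0.05,
                 low_percentile: float = 1.0):
        if index not in ("green", "purple", "auto"):
            raise ValueError("index must be 'green', 'purple' or 'auto'")
        self.index = index
        self.min_contrast = min_contrast
        self.low_percentile = low_percentile

    def _rescale(self, idx: np.ndarray) -> np.ndarray:
        lo = np.percentile(idx, self.low_percentile)
        span = idx.max() - lo
        if span < self.min_contrast:
            return np.zeros(idx.shape, dtype=float)
        # upper reference = median of candidate plant pixels, not the crop
        # max: the max sits several noise sigmas above the typical plant
        # pixel and would drag it toward the 0.5 threshold
        hi = float(np.median(idx[idx > lo + 0.3 * span]))
        if hi - lo < self.min_contrast:
            return np.zeros(idx.shape, dtype=float)
        return np.clip((idx - lo) / (hi - lo), 0.0, 1.0)

    def __call__(self, crop: np.ndarray) -> np.ndarray:
        rgb = np.asarray(crop, dtype=float)
        tot = rgb.sum(axis=2)
        chrom = np.divide(rgb, tot[:, :, None],
                          out=np.zeros_like(rgb), where=tot[:, :, None] > 0)
        r, g, b = chrom[:, :, 0], chrom[:, :, 1], chrom[:, :, 2]
        exg = 2 * g - r - b
        if self.index == "green":
            return self._rescale(exg)
        if self.index == "purple":
            return self._rescale(-exg)
        maps = [self._rescale(exg), self._rescale(-exg)]
        # the correct index highlights the minority (plant) pixels
        fracs = [float((m > 0.5).mean()) for m in maps]
        return maps[int(np.argmin(fracs))]


def segment_plant(crop: np.ndarray,
                  backend: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Run a segmentation backend, validating its probability-map contract."""
    if crop.ndim != 3 or crop.shape[2] != 3:
        raise ValueError("crop must be an RGB image")
    pmap = np.asarray(backend(crop), dtype=float)
    if pmap.shape != crop.shape[:2]:
        raise RuntimeError("backend returned a map on the wrong grid")
    if pmap.min() < 0.0 or pmap.max() > 1.0:
        raise RuntimeError("backend probabilities must lie in [0, 1]")
    return pmap


def binarize_and_select(pmap: np.ndarray, threshold: float = 0.5,
                        circle: tuple[float, float, float] | None = None,
                        connectivity: int = 1) -> PlantMask:
    """Threshold the probability map and keep the main plant structure.

    Pixels strictly above ``threshold`` are labeled (4-connected by default)
    and only the largest-area component is kept; the result is then clipped
    to the pot circle, so the mask is always a subset of the phenotyping
    region.  An empty result is a valid (empty) mask.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    binary = np.asarray(pmap, dtype=float) > threshold
    lab, n = label(binary, connectivity=connectivity, return_num=True)
    if n == 0:
        return PlantMask(np.zeros_like(binary), circle, 0)
    areas = np.bincount(lab.ravel())[1:]
    main = lab == (int(np.argmax(areas)) + 1)
    if circle is not None:
        cx, cy, r = circle
        rows = np.arange(main.shape[0])[:, None] - cy
        cols = np.arange(main.shape[1])[None, :] - cx
        main &= np.hypot(cols, rows) <= r
    return PlantMask(main, circle, n)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks (1.0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
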