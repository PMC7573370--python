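"""Pot detection, semantic filtering, and cross-frame localization.

The detector itself is a pluggable backend: any callable mapping a
:class:`CameraFrame` to a list of :class:`Detection`.  The bundled
:class:`HoughPotDetector` baseline matches circles at the known pot radius
over a Canny edge map and reports the normalized Hough accumulator response
as its confidence.  Everything downstream — confidence thresholding, greedy
NMS, strict ROI containment, duplicate resolution across overlapping frames,
best-frame selection, and variety/plant index assignment from the planting
layout — is backend-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "CameraFrame",
    "Detection",
    "DetectionConfig",
    "PotRecord",
    "HoughPotDetector",
    "clean_frames",
    "calibrate_scale",
    "detect_pots",
    "filter_detections",
    "localize_pots",
    "estimate_pot_size",
    "write_annotations",
    "read_annotations",
]


@dataclass
class CameraFrame:
    """One top-view RGB frame with its gantry position and scale."""

    frame_id: str
    image: np.ndarray               # uint8, H×W×3
    x_mm: float | None
    y_mm: float | None
    timestamp: float
    mm_per_px: float
    day: int | None = None
    route_id: str | None = None

    def __post_init__(self) -> None:
        if self.mm_per_px is not None and self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.image is not None and self.image.size == 0:
            raise ValueError("empty image")


@dataclass(frozen=True)
class Detection:
    """A candidate box in normalized [0, 1] frame coordinates."""

    cx: float
    cy: float
    w: float
    h: float
    confidence: float
    label: str = "pot"

    def corners(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass(frozen=True)
class DetectionConfig:
    """Semantic-filtering parameters.

    ``roi`` is an inset rectangle (x0, y0, x1, y1) in normalized frame
    coordinates; only boxes strictly inside it survive.  When None, the ROI
    defaults to the frame inset by one nominal pot radius per side, which
    guarantees retained boxes are complete pots.
    """

    confidence_threshold: float = 0.9
    nms_iou: float = 0.45
    roi: tuple[float, float, float, float] | None = None
    pot_diameter_mm: float = 320.0
    crop_margin: float = 0.15
    merge_radius_mm: float | None = None   # None → pot diameter / 2

    def __post_init__(self) -> None:
        for v in (self.confidence_threshold, self.nms_iou):
            if not (0.0 <= v <= 1.0):
                raise ValueError("thresholds must be in [0, 1]")

    def resolved_roi(self, frame_px: int, mm_per_px: float
                     ) -> tuple[float, float, float, float]:
        if self.roi is not None:
            return self.roi
        inset = (self.pot_diameter_mm / 2.0 / mm_per_px) / frame_px
        return (inset, inset, 1.0 - inset, 1.0 - inset)


@dataclass
class PotRecord:
    """A detected pot resolved to global coordinates and plant identity."""

    pot_id: int
    x_mm: float
    y_mm: float
    diameter_mm: float
    variety: str
    plant: str
    best_frame: str
    center_dist_px: float
    crop: np.ndarray | None = None
    circle: tuple[float, float, float] | None = None   # (cx, cy, r) px in crop
    crop_box_px: tuple[int, int, int, int] | None = None  # frame-local r0,c0,r1,c1
    unmatched: bool = False


def clean_frames(frames: Sequence[CameraFrame],
                 overlap: float = 0.25) -> list[CameraFrame]:
    """Drop redundant frames of the same spot on the route.

    Frames are binned on a position grid whose cell equals the frame
    footprint × (1 − overlap); the earliest frame per occupied cell is kept.
    """
    missing = [f.frame_id for f in frames if f.x_mm is None or f.y_mm is None]
    if missing:
        raise ValueError(f"frames with missing gantry positions: {missing}")
    if not frames:
        return []
    kept: dict[tuple[int, int], CameraFrame] = {}
    for f in sorted(frames, key=lambda f: f.timestamp):
        cell_mm = f.image.shape[1] * f.mm_per_px * (1.0 - overlap)
        key = (int(round(f.x_mm / cell_mm)), int(round(f.y_mm / cell_mm)))
        if key in kept:
            logger.info("clean_frames: dropping redundant frame %s (cell %s)",
                        f.frame_id, key)
        else:
            kept[key] = f
    return list(kept.values())


def calibrate_scale(true_size_mm: float, detected_size_px: float) -> float:
    """mm-per-pixel from a calibration object of known physical size."""
    if detected_size_px <= 0:
        raise ValueError("detected size must be positive")
    return true_size_mm / detected_size_px


class HoughPotDetector:
    """Classical baseline detector: Canny edges + circular Hough transform.

    Searches radii within ``radius_tol`` of the nominal pot radius and emits
    one detection per accumulator peak, with confidence equal to the
    normalized accumulator value (fraction of the circle perimeter supported
    by edge pixels; ≈1 for a clean rim).
    """

    def __init__(self, pot_diameter_mm: float = 320.0, radius_tol: float = 0.08,
                 canny_sigma: float = 1.5, max_pots: int = 64):
        self.pot_diameter_mm = pot_diameter_mm
        self.radius_tol = radius_tol
        self.canny_sigma = canny_sigma
        self.max_pots = max_pots

    def __call__(self, frame: CameraFrame) -> list[Detection]:
        r_nom = self.pot_diameter_mm / 2.0 / frame.mm_per_px
        lo = max(3, int(np.floor(r_nom * (1 - self.radius_tol))))
        hi = int(np.ceil(r_nom * (1 + self.radius_tol)))
        radii = np.arange(lo, hi + 1)
        edges = canny(rgb2gray(frame.image), sigma=self.canny_sigma)
        accum = hough_circle(edges, radii)
        h, w = frame.image.shape[:2]
        _conf, cx, cy, rad = hough_circle_peaks(
            accum, radii,
            min_xdistance=int(r_nom), min_ydistance=int(r_nom),
            total_num_peaks=self.max_pots, threshold=0.25)
        out = []
        for x, y, _r in zip(cx, cy, rad):
            # a rim yields two concentric edge circles (inner and outer
            # wall); the pot diameter is the outer one, so take the largest
            # radius whose edge support is close to the best
            support = {float(r): self._support(edges, float(x), float(y),
                                               float(r), radial_tol=1.0)
                       for r in radii}
            best = max(support.values())
            if best <= 0:
                continue
            r_outer = max(r for r, s in support.items() if s >= 0.97 * best)
            out.append(Detection(
                cx=float(x) / w, cy=float(y) / h,
                w=2.0 * r_outer / w, h=2.0 * r_outer / h,
                confidence=support[r_outer]))
        return out

    @staticmethod
    def _support(edges: np.ndarray, cx: float, cy: float, r: float,
                 n_angles: int = 360, radial_tol: float = 1.5) -> float:
        """Fraction of the circle's angular bins backed by an edge pixel.

        A cleaner confidence than the raw accumulator value, which loses
        10–20% to radial discretization even on a perfect rim.
        """
        h, w = edges.shape
        theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
        hit = np.zeros(n_angles, dtype=bool)
        for dr in np.arange(-radial_tol, radial_tol + 0.5, 0.5):
            x = np.clip(np.round(cx + (r + dr) * np.cos(theta)), 0, w - 1)
            y = np.clip(np.round(cy + (r + dr) * np.sin(theta)), 0, h - 1)
            hit |= edges[y.astype(int), x.astype(int)]
        return float(hit.mean())


def detect_pots(frame: CameraFrame,
                backend: Callable[[CameraFrame], list[Detection]]
                ) -> list[Detection]:
    """Run a detection backend on one frame, tagging failures with its id."""
    try:
        return list(backend(frame))
    except Exception as exc:                      # noqa: BLE001
        raise RuntimeError(
            f"detection backend failed on frame {frame.frame_id}") from exc


def _iou(a: Detection, b: Detection) -> float:
    ax0, ay0, ax1, ay1 = a.corners()
    bx0, by0, bx1, by1 = b.corners()
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union > 0 else 0.0


def filter_detections(dets: Sequence[Detection],
                      cfg: DetectionConfig,
                      frame_px: int | None = None,
                      mm_per_px: float | None = None) -> list[Detection]:
    """Semantic filtering: confidence threshold → greedy NMS → strict ROI.

    The ROI check needs frame geometry only when ``cfg.roi`` is None (the
    default inset-by-a-pot-radius ROI); pass ``frame_px``/``mm_per_px`` then.
    """
    survivors = [d for d in dets if d.confidence >= cfg.confidence_threshold]
    survivors.sort(key=lambda d: -d.confidence)
    kept: list[Detection] = []
    for d in survivors:
        if all(_iou(d, k) <= cfg.nms_iou for k in kept):
            kept.append(d)
    if cfg.roi is None and (frame_px is None or mm_per_px is None):
        roi = (0.0, 0.0, 1.0, 1.0)
    else:
        roi = cfg.resolved_roi(frame_px or 1, mm_per_px or 1.0)
    x0, y0, x1, y1 = roi
    return [
        d for d in kept
        if d.cx - d.w / 2 > x0 and d.cy - d.h / 2 > y0
        and d.cx + d.w / 2 < x1 and d.cy + d.h / 2 < y1
    ]


def _to_global_mm(det: Detection, frame: CameraFrame,
                  y_flip: bool = False) -> tuple[float, float]:
    h, w = frame.image.shape[:2]
    dx = (det.cx * w - w / 2.0) * frame.mm_per_px
    dy = (det.cy * h - h / 2.0) * frame.mm_per_px
    if y_flip:
        dy = -dy
    return frame.x_mm + dx, frame.y_mm + dy


def localize_pots(
    detections: Mapping[str, Sequence[Detection]],
    frames: Sequence[CameraFrame],
    layout: pd.DataFrame,
    cfg: DetectionConfig | None = None,
    y_flip: bool = False,
) -> tuple[list[PotRecord], list[PotRecord]]:
    """Resolve per-frame detections into one record per physical pot.

    Detections are mapped to global mm coordinates (gantry position + local
    offset × scale), merged when closer than half a pot diameter, and the
    representative instance per pot is the one closest to its frame centre
    (least imaging distortion).  Variety/plant indices come from the nearest
    planting-layout cell; pots farther than half the grid spacing from any
    cell are returned separately as unmatched error records.

    Returns ``(records, unmatched)``.
    """
    cfg = cfg or DetectionConfig()
    frame_by_id = {f.frame_id: f for f in frames}
    scales = {f.mm_per_px for f in frames}
    if len(scales) > 1:
        raise ValueError("frames must share one mm-per-px scale")

    # flatten to candidate instances
    cand = []  # (x_mm, y_mm, diam_mm, dist_px, frame_id, det)
    for fid, dets in detections.items():
        fr = frame_by_id[fid]
        h, w = fr.image.shape[:2]
        for d in dets:
            gx, gy = _to_global_mm(d, fr, y_flip)
            diam = d.w * w * fr.mm_per_px
            dist = np.hypot(d.cx * w - w / 2.0, d.cy * h - h / 2.0)
            cand.append((gx, gy, diam, dist, fid, d))

    merge_r = cfg.merge_radius_mm or cfg.pot_diameter_mm / 2.0
    clusters: list[list[int]] = []
    centers: list[tuple[float, float]] = []
    for i, (gx, gy, *_rest) in enumerate(cand):
        for ci, (mx, my) in enumerate(centers):
            if np.hypot(gx - mx, gy - my) < merge_r:
                clusters[ci].append(i)
                n = len(clusters[ci])
                centers[ci] = (mx + (gx - mx) / n, my + (gy - my) / n)
                break
        else:
            clusters.append([i])
            centers.append((gx, gy))

    # half the grid spacing = half the minimum nearest-neighbour distance
    lx, ly = layout["x_mm"].to_numpy(float), layout["y_mm"].to_numpy(float)
    if len(lx) > 1:
        dmat = np.hypot(lx[:, None] - lx[None, :], ly[:, None] - ly[None, :])
        np.fill_diagonal(dmat, np.inf)
        max_match = float(dmat.min()) / 2.0
    else:
        max_match = merge_r

    records: list[PotRecord] = []
    unmatched: list[PotRecord] = []
    for pot_id, members in enumerate(clusters):
        best = min(members, key=lambda i: cand[i][3])
        gx, gy, diam, dist, fid, det = cand[best]
        fr = frame_by_id[fid]
        h, w = fr.image.shape[:2]
        # crop = detection box dilated by the configured margin
        bw, bh = det.w * w, det.h * h
        m = cfg.crop_margin
        r0 = max(0, int(round((det.cy - det.h / 2) * h - m * bh)))
        r1 = min(h, int(round((det.cy + det.h / 2) * h + m * bh)))
        c0 = max(0, int(round((det.cx - det.w / 2) * w - m * bw)))
        c1 = min(w, int(round((det.cx + det.w / 2) * w + m * bw)))
        crop = fr.image[r0:r1, c0:c1].copy()
        circle = (det.cx * w - c0, det.cy * h - r0, det.w * w / 2.0)

        d2 = np.hypot(lx - gx, ly - gy)
        j = int(np.argmin(d2)) if len(d2) else -1
        rec = PotRecord(
            pot_id=pot_id, x_mm=gx, y_mm=gy, diameter_mm=diam,
            variety="?", plant="?", best_frame=fid, center_dist_px=dist,
            crop=crop, circle=circle, crop_box_px=(r0, c0, r1, c1))
        if j >= 0 and d2[j] <= max_match:
            rec.variety = str(layout["variety"].iloc[j])
            rec.plant = str(layout["plant"].iloc[j])
            records.append(rec)
        else:
            rec.unmatched = True
            unmatched.append(rec)
    return records, unmatched


def estimate_pot_size(records: Sequence[PotRecord],
                      nominal_diameter_mm: float = 320.0
                      ) -> tuple[float, float]:
    """Mean detected diameter (mm) and max relative deviation from nominal."""
    if not records:
        raise ValueError("no pot records")
    d = np.array([r.diameter_mm for r in records], dtype=float)
    rel = np.abs(d - nominal_diameter_mm) / nominal_diameter_mm
    return float(d.mean()), float(rel.max())


def write_annotations(path: str | Path, dets: Iterable[Detection],
                      precision: int = 6) -> None:
    """One line per box: ``class x_center y_center width height`` (normalized)."""
    lines = [
        f"0 {d.cx:.{precision}f} {d.cy:.{precision}f} "
        f"{d.w:.{precision}f} {d.h:.{precision}f}"
        for d in dets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotations(path: str | Path, confidence: float = 1.0
                     ) -> list[Detection]:
    dets = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        _cls, cx, cy, w, h = parts[:5]
        dets.append(Detection(cx=float(cx), cy=float(cy), w=float(w),
                              h=float(h), confidence=confidence))
    return dets
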