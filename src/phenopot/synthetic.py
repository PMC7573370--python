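"""Synthetic top-view greenhouse scenes with exact ground truth.

Emulates the data a gantry-mounted camera collects over a bed of potted
rosette plants (e.g. lettuce): circular pots of known diameter on a textured
floor, plants rendered as polar cosine-lobed rosettes r(θ) = R·(1 + a·cos kθ)
growing along a logistic radius trajectory, and overlapping camera frames
cropped from one global canvas along a planned route.  Every scene carries
pixel-exact plant masks and trait values computed by the independent
brute-force path in :mod:`phenopot.truth`, so the whole measurement pipeline
can be validated without real imagery.

Default geometry mirrors a real installation: 32 cm pots, 1.067 mm/px,
2016 px frames, eight-plus acquisition days spanning a 34-day vegetative
window.  Tests and examples typically use coarser scales for speed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import truth
from .detection import CameraFrame
from .traits import TRAIT_NAMES

__all__ = [
    "SceneConfig",
    "RosetteParams",
    "SceneGroundTruth",
    "PotTruth",
    "generate_scene",
    "grow_series",
    "rosette_mask",
    "route_positions",
    "default_varieties",
]

# palette used by default_varieties: light green, dark green, purple
_COLORS = ((96, 168, 74), (48, 110, 52), (118, 58, 128))


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and schedule of one synthetic greenhouse scene."""

    canvas_px: int | None = None          # None → sized to fit the pot grid
    mm_per_px: float = 1.067
    grid_rows: int = 2
    grid_cols: int = 2
    spacing_mm: float = 400.0
    pot_diameter_mm: float = 320.0
    frame_px: int = 2016
    overlap: float = 0.25
    days: tuple[int, ...] = (0, 5, 9, 13, 17, 22, 26, 30, 34)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("frame overlap fraction must be in [0, 1)")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if tuple(sorted(self.days)) != tuple(self.days):
            raise ValueError("days must be sorted ascending")
        if self.frame_px < self.pot_diameter_px:
            raise ValueError(
                "frame smaller than a pot: no frame can fully contain a pot")

    @property
    def pot_radius_px(self) -> float:
        return self.pot_diameter_mm / 2.0 / self.mm_per_px

    @property
    def pot_diameter_px(self) -> float:
        return self.pot_diameter_mm / self.mm_per_px

    def resolved_canvas_px(self) -> int:
        if self.canvas_px is not None:
            return int(self.canvas_px)
        extent_x = (self.grid_cols - 1) * self.spacing_mm / self.mm_per_px
        extent_y = (self.grid_rows - 1) * self.spacing_mm / self.mm_per_px
        # border per side ≥ 2 pot radii + guard, so a frame can contain an
        # edge pot with full ROI clearance without clamping off-canvas
        need = max(extent_x, extent_y) + 2 * (self.pot_diameter_px + 8)
        return int(max(np.ceil(need), self.frame_px))

    def pot_centers_mm(self) -> np.ndarray:
        """(n_pots, 2) array of (x, y) pot centers in mm, row-major order."""
        canvas_mm = self.resolved_canvas_px() * self.mm_per_px
        x0 = (canvas_mm - (self.grid_cols - 1) * self.spacing_mm) / 2.0
        y0 = (canvas_mm - (self.grid_rows - 1) * self.spacing_mm) / 2.0
        centers = [
            (x0 + c * self.spacing_mm, y0 + r * self.spacing_mm)
            for r in range(self.grid_rows)
            for c in range(self.grid_cols)
        ]
        return np.asarray(centers, dtype=float)


@dataclass(frozen=True)
class RosetteParams:
    """One variety's growth and appearance model.

    The plant silhouette is the polar curve r(θ) = R(t)·(1 + a·cos kθ); the
    base radius R(t) follows a logistic trajectory
    R(t) = r_max / (1 + exp(−g·(t − t₀)))  (mm), which is non-decreasing for
    g > 0.  ``radius_fn`` overrides the trajectory (for analytic test cases).
    """

    r_max_mm: float = 140.0
    growth_rate: float = 0.18        # logistic slope, 1/day
    inflection_day: float = 14.0
    lobe_count: int = 6
    lobe_amplitude: float = 0.12
    rotation_rad: float = 0.0
    color: tuple[int, int, int] = (96, 168, 74)
    color_noise_sd: float = 8.0
    name: str | None = None
    radius_fn: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.lobe_amplitude < 0.6):
            raise ValueError("lobe amplitude must be in [0, 0.6)")
        if any(not (0 <= c <= 255) for c in self.color):
            raise ValueError("color channels must be in [0, 255]")
        if self.growth_rate < 0:
            raise ValueError("growth rate must be non-negative")

    def radius_mm(self, day: float) -> float:
        if self.radius_fn is not None:
            return float(self.radius_fn(day))
        return self.r_max_mm / (
            1.0 + np.exp(-self.growth_rate * (day - self.inflection_day)))


@dataclass
class PotTruth:
    index: int
    center_mm: tuple[float, float]
    variety: str
    plant: str
    params: RosetteParams


@dataclass
class SceneGroundTruth:
    """Everything the generator knows about a scene.

    ``masks[(pot_index, day)]`` is ``(row0, col0, mask)``: a boolean plant
    mask in a crop of the global canvas whose top-left corner sits at
    (row0, col0).  ``traits`` holds the brute-force trait values, one row per
    (variety, plant, day).
    """

    config: SceneConfig
    pots: list[PotTruth]
    masks: dict[tuple[int, int], tuple[int, int, np.ndarray]]
    traits: pd.DataFrame
    canvas_px: int = 0

    def layout(self) -> pd.DataFrame:
        """Planting-layout map: global position → variety/plant indices."""
        return pd.DataFrame(
            {
                "x_mm": [p.center_mm[0] for p in self.pots],
                "y_mm": [p.center_mm[1] for p in self.pots],
                "variety": [p.variety for p in self.pots],
                "plant": [p.plant for p in self.pots],
            }
        )

    def canvas_mask(self, pot_index: int, day: int) -> np.ndarray:
        """Plant mask embedded in full-canvas coordinates."""
        r0, c0, m = self.masks[(pot_index, day)]
        out = np.zeros((self.canvas_px, self.canvas_px), dtype=bool)
        out[r0:r0 + m.shape[0], c0:c0 + m.shape[1]] = m
        return out


def route_positions(canvas_px: int, frame_px: int, overlap: float) -> list[int]:
    """Frame-center coordinates (px) of the gantry route along one axis."""
    half = frame_px / 2.0
    stride = max(1, int(round(frame_px * (1.0 - overlap))))
    last = canvas_px - half
    pos = list(np.arange(half, last + 1e-9, stride))
    if not pos or pos[-1] < last - 1e-9:
        pos.append(last)
    return [int(round(p)) for p in pos]


def rosette_mask(shape: tuple[int, int], center_px: tuple[float, float],
                 radius_px: float, lobe_amplitude: float, lobe_count: int,
                 rotation_rad: float = 0.0) -> np.ndarray:
    """Rasterize r(θ) = R·(1 + a·cos k(θ − rot)) on pixel centers."""
    rows = np.arange(shape[0])[:, None] - center_px[1]
    cols = np.arange(shape[1])[None, :] - center_px[0]
    rho = np.hypot(cols, rows)
    theta = np.arctan2(rows, cols)
    boundary = radius_px * (
        1.0 + lobe_amplitude * np.cos(lobe_count * (theta - rotation_rad)))
    return rho <= boundary


def grow_series(params: RosetteParams, days: Sequence[float]) -> pd.DataFrame:
    """Analytic per-day radius and projected area for one variety.

    Returns columns ``day``, ``radius_mm`` and ``PA`` (cm²), the latter from
    the closed-form rosette area πR²(1 + a²/2).
    """
    days = list(days)
    if days != sorted(days):
        raise ValueError("time points must be sorted ascending")
    radii = np.array([params.radius_mm(d) for d in days])
    pa_cm2 = np.array(
        [truth.rosette_area_mm2(r, params.lobe_amplitude) / 100.0 for r in radii])
    return pd.DataFrame({"day": days, "radius_mm": radii, "PA": pa_cm2})


def default_varieties(n: int, seed: int = 0,
                      palette: str = "green") -> list[RosetteParams]:
    """A plausible mix of rosette varieties with seeded growth parameters.

    ``palette='green'`` alternates light- and dark-green leaf colors (the
    default excess-green segmentation baseline assumes green foliage);
    ``palette='mixed'`` adds a purple variety, which needs the purple or
    auto index backend.  Growth ranges emulate vegetative growth after
    transplanting month-old seedlings: initial canopy radius ≈ 20–30 mm,
    final radius 90–125 mm within a 34-day window, and the lobed silhouette
    kept inside the 160 mm pot radius (r_max·(1+a) ≤ 150 mm).
    """
    colors = _COLORS[:2] if palette == "green" else _COLORS
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(RosetteParams(
            r_max_mm=float(rng.uniform(90.0, 125.0)),
            growth_rate=float(rng.uniform(0.10, 0.16)),
            inflection_day=float(rng.uniform(4.0, 8.0)),
            lobe_count=int(rng.integers(5, 9)),
            lobe_amplitude=float(rng.uniform(0.05, 0.2)),
            rotation_rad=float(rng.uniform(0, 2 * np.pi)),
            color=colors[i % len(colors)],
            name=f"C-{i % len(colors) + 1}",
        ))
    return out


def _render_background(cfg: SceneConfig, canvas_px: int) -> np.ndarray:
    """Floor texture (low-amplitude noise + grid lines) and empty pots."""
    rng = np.random.default_rng([cfg.seed, 97])
    img = np.empty((canvas_px, canvas_px, 3), dtype=float)
    base = np.array([120.0, 119.0, 117.0])
    noise = rng.uniform(-10, 10, size=(canvas_px, canvas_px))
    img[:] = base[None, None, :] + noise[:, :, None]
    # faint bench grid lines every 500 mm
    step = max(8, int(round(500.0 / cfg.mm_per_px)))
    for k in range(0, canvas_px, step):
        img[k:k + 2, :, :] = 100.0
        img[:, k:k + 2, :] = 100.0

    r_pot = cfg.pot_radius_px
    rim_w = max(3.0, 8.0 / cfg.mm_per_px)
    soil_noise = rng.uniform(-8, 8, size=(canvas_px, canvas_px))
    for cx_mm, cy_mm in cfg.pot_centers_mm():
        cx, cy = cx_mm / cfg.mm_per_px, cy_mm / cfg.mm_per_px
        half = int(np.ceil(r_pot)) + 2
        r0, r1 = max(0, int(cy) - half), min(canvas_px, int(cy) + half + 1)
        c0, c1 = max(0, int(cx) - half), min(canvas_px, int(cx) + half + 1)
        rows = np.arange(r0, r1)[:, None] - cy
        cols = np.arange(c0, c1)[None, :] - cx
        d = np.hypot(cols, rows)
        rim = (d <= r_pot) & (d > r_pot - rim_w)
        soil = d <= r_pot - rim_w
        sub = img[r0:r1, c0:c1]
        sub[rim] = np.array([58.0, 58.0, 60.0])
        sub[soil] = (np.array([108.0, 88.0, 66.0])[None, :]
                     + soil_noise[r0:r1, c0:c1][soil, None])
        img[r0:r1, c0:c1] = sub
    return img


def generate_scene(
    config: SceneConfig,
    varieties: Sequence[RosetteParams],
) -> tuple[list[CameraFrame], SceneGroundTruth]:
    """Render a full scene and return its frames plus exact ground truth.

    One :class:`RosetteParams` per pot (row-major grid order).  Frames are
    crops of a single rendered canvas at the gantry route positions, so a
    pot looks identical in every frame that sees it; supplemental frames
    centred on any pot the base route does not fully contain guarantee that
    every pot appears complete in at least one frame.
    """
    n_pots = config.grid_rows * config.grid_cols
    if len(varieties) != n_pots:
        raise ValueError(
            f"grid has {n_pots} pots but {len(varieties)} variety assignments")

    canvas_px = config.resolved_canvas_px()
    s = config.mm_per_px
    centers_mm = config.pot_centers_mm()
    background = _render_background(config, canvas_px)

    pots = []
    for i, (params, (cx, cy)) in enumerate(zip(varieties, centers_mm)):
        variety = params.name or f"C-{i + 1}"
        pots.append(PotTruth(i, (float(cx), float(cy)), variety,
                             f"P-{i + 1}", params))

    # gantry route (same every day); add supplemental frames for any pot the
    # base route does not contain with enough margin.  The margin is two pot
    # radii where the frame allows it, so every pot's box also clears the
    # default detection ROI (frame inset by one pot radius per side).
    xs = route_positions(canvas_px, config.frame_px, config.overlap)
    ys = route_positions(canvas_px, config.frame_px, config.overlap)
    route = [(x, y) for y in ys for x in xs]
    half_f = config.frame_px / 2.0
    r_pot = config.pot_radius_px
    # small guard beyond 2 r_pot: detected boxes can exceed the true rim by
    # a pixel or two and ROI containment is strict
    margin = (2.0 * r_pot + 4.0 if config.frame_px >= 4.0 * r_pot + 8.0
              else r_pot)
    for cx_mm, cy_mm in centers_mm:
        cx, cy = cx_mm / s, cy_mm / s
        contained = any(
            abs(cx - fx) <= half_f - margin and abs(cy - fy) <= half_f - margin
            for fx, fy in route)
        if not contained:
            fx = int(round(min(max(cx, half_f), canvas_px - half_f)))
            fy = int(round(min(max(cy, half_f), canvas_px - half_f)))
            route.append((fx, fy))

    frames: list[CameraFrame] = []
    masks: dict[tuple[int, int], tuple[int, int, np.ndarray]] = {}
    trait_rows = []

    for day in config.days:
        canvas = background.copy()
        rng = np.random.default_rng([config.seed, 1, int(day)])
        for pot in pots:
            p = pot.params
            r_mm = p.radius_mm(day)
            r_px = r_mm / s
            cx, cy = pot.center_mm[0] / s, pot.center_mm[1] / s
            half = int(np.ceil(max(r_px * (1 + p.lobe_amplitude), 1.0))) + 2
            r0, r1 = max(0, int(cy) - half), min(canvas_px, int(cy) + half + 1)
            c0, c1 = max(0, int(cx) - half), min(canvas_px, int(cx) + half + 1)
            m = rosette_mask((r1 - r0, c1 - c0), (cx - c0, cy - r0), r_px,
                             p.lobe_amplitude, p.lobe_count, p.rotation_rad)
            masks[(pot.index, day)] = (r0, c0, m)
            npx = int(m.sum())
            if npx:
                noise = rng.normal(0.0, p.color_noise_sd, size=(npx, 3))
                canvas[r0:r1, c0:c1][m] = np.clip(
                    np.asarray(p.color, dtype=float)[None, :] + noise, 0, 255)

            # ground-truth traits via the independent brute-force path
            if npx:
                geo = truth.mask_geometry(m, s, pot_radius_px=r_pot)
                geo["PP"] = truth.rosette_arc_length_mm(
                    r_mm, p.lobe_amplitude, p.lobe_count) / 10.0
                crop = np.clip(canvas[r0:r1, c0:c1], 0, 255)
                px = crop[m]
                rr, gg, bb = px.mean(axis=0)
                h, sat, v = truth.hsv_means(crop.astype(np.uint8), m)
                tot = px.sum(axis=1)
                chrom = np.divide(px, tot[:, None], out=np.zeros_like(px),
                                  where=tot[:, None] > 0)
                exg = float(np.mean(2 * chrom[:, 1] - chrom[:, 0] - chrom[:, 2]))
                row = dict(variety=pot.variety, plant=pot.plant, day=day,
                           R=rr, G=gg, B=bb, H=h, S=sat, V=v, ExG=exg, **geo)
                trait_rows.append(row)

        canvas_u8 = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
        for j, (fx, fy) in enumerate(route):
            r0 = int(round(fy - half_f))
            c0 = int(round(fx - half_f))
            img = canvas_u8[r0:r0 + config.frame_px, c0:c0 + config.frame_px]
            frames.append(CameraFrame(
                frame_id=f"d{int(day):03d}_f{j:03d}",
                image=img.copy(),
                x_mm=fx * s,
                y_mm=fy * s,
                timestamp=float(day) * 86400.0 + j,
                mm_per_px=s,
                day=int(day),
                route_id=f"f{j:03d}",
            ))

    cols = ["variety", "plant", "day"] + list(TRAIT_NAMES)
    traits = pd.DataFrame(trait_rows)
    if len(traits):
        traits = traits[cols]
    gt = SceneGroundTruth(config=config, pots=pots, masks=masks,
                          traits=traits, canvas_px=canvas_px)
    return frames, gt
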