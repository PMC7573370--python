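"""File interchange: frames + manifest, masks, layout and trait tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detection import CameraFrame, PotRecord

__all__ = [
    "save_frames", "load_frames", "save_mask", "load_mask",
    "save_pot_records", "save_layout", "load_layout",
]


def save_frames(frames: Sequence[CameraFrame], out_dir: str | Path) -> Path:
    """Write frames as PNG plus a frames-manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in frames:
        iio.imwrite(out / f"{f.frame_id}.png", f.image)
        rows.append({"frame_id": f.frame_id, "x_mm": f.x_mm, "y_mm": f.y_mm,
                     "timestamp": f.timestamp, "day": f.day,
                     "mm_per_px": f.mm_per_px, "route_id": f.route_id})
    manifest = out / "frames.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_frames(manifest: str | Path) -> list[CameraFrame]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    frames = []
    for _, row in df.iterrows():
        img = iio.imread(manifest.parent / f"{row.frame_id}.png")
        day = None if pd.isna(row.get("day")) else int(row["day"])
        frames.append(CameraFrame(
            frame_id=str(row["frame_id"]), image=img,
            x_mm=float(row["x_mm"]), y_mm=float(row["y_mm"]),
            timestamp=float(row["timestamp"]), mm_per_px=float(row["mm_per_px"]),
            day=day, route_id=str(row.get("route_id", "")) or None))
    return frames


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """8-bit PNG, 0 background / 255 plant."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)) > 127


def save_pot_records(records: Sequence[PotRecord], path: str | Path) -> None:
    pd.DataFrame([
        {"pot_id": r.pot_id, "variety": r.variety, "plant": r.plant,
         "x_mm": r.x_mm, "y_mm": r.y_mm, "diameter_mm": r.diameter_mm,
         "best_frame": r.best_frame, "center_dist_px": r.center_dist_px}
        for r in records
    ]).to_csv(path, index=False)


def save_layout(layout: pd.DataFrame, path: str | Path) -> None:
    layout.to_csv(path, index=False)


def load_layout(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
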