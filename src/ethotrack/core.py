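"""Shared containers: frames, frame sequences, track points and trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FrameSequence", "TrackPoint", "Trajectory", "TRAJECTORY_COLUMNS"]


@dataclass
class FrameSequence:
    """Timestamped stack of single-channel frames.

    ``frames`` is an (n, H, W) uint8 array; ``timestamps`` holds seconds since
    experiment start and must be strictly increasing but need not be uniform —
    real-time tracking runs at a variable 1–4 FPS depending on load, and the
    pipeline must tolerate that.
    """

    frames: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be an (n, H, W) array")
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> tuple[float, np.ndarray]:
        return float(self.timestamps[i]), self.frames[i]

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class TrackPoint:
    """Per-frame fly state in one ROI.

    ``x, y`` are pixels in the ROI crop frame; ``x_mm`` is the distance from
    the food end along the tube axis.  ``w >= h`` are the fitted ellipse axes
    (full lengths, px) and ``phi`` its orientation in degrees, reported modulo
    180 because image moments cannot tell head from tail.  ``is_inferred``
    marks frames where no blob was found and the previous position was carried
    forward.
    """

    t: float
    x: float
    y: float
    x_mm: float
    w: float
    h: float
    phi: float
    is_inferred: bool = False

    def __post_init__(self) -> None:
        if not self.is_inferred and not (self.w >= self.h > 0):
            raise ValueError(f"ellipse axes must satisfy w >= h > 0, got {self.w}, {self.h}")


TRAJECTORY_COLUMNS = ["t", "x", "y", "x_mm", "w", "h", "phi", "is_inferred"]


class Trajectory:
    """Ordered track points for a single fly in a single ROI."""

    def __init__(
        self,
        df: pd.DataFrame,
        roi_index: int,
        mm_per_px: float,
        crop_origin: tuple[float, float] = (0.0, 0.0),
    ):
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        t = df["t"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory timestamps must be strictly increasing")
        self.df = df.reset_index(drop=True)
        self.roi_index = int(roi_index)
        self.mm_per_px = float(mm_per_px)
        self.crop_origin = (float(crop_origin[0]), float(crop_origin[1]))

    @classmethod
    def from_points(
        cls,
        points: list[TrackPoint],
        roi_index: int,
        mm_per_px: float,
        crop_origin: tuple[float, float] = (0.0, 0.0),
    ) -> "Trajectory":
        df = pd.DataFrame(
            [
                {
                    "t": p.t,
                    "x": p.x,
                    "y": p.y,
                    "x_mm": p.x_mm,
                    "w": p.w,
                    "h": p.h,
                    "phi": p.phi,
                    "is_inferred": p.is_inferred,
                }
                for p in points
            ],
            columns=TRAJECTORY_COLUMNS,
        )
        return cls(df, roi_index, mm_per_px, crop_origin)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy(dtype=float)

    @property
    def xy_px(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def xy_global_px(self) -> np.ndarray:
        return self.xy_px + np.asarray(self.crop_origin)

    @property
    def x_mm(self) -> np.ndarray:
        return self.df["x_mm"].to_numpy(dtype=float)

    @property
    def is_inferred(self) -> np.ndarray:
        return self.df["is_inferred"].to_numpy(dtype=bool)
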