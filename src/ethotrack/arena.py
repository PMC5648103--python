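"""Arena templates: fiducial geometry and ROI layout in physical (mm) coordinates.

An arena template is the machine-readable description of a behavioral arena:
the positions of its 3 printed reference marks (fiducials), the rectangular
tube regions (ROIs) it lodges, and the nominal mm-per-pixel calibration at
which it is imaged.  Templates live in mm coordinates; registration maps them
into image pixels.

Conventions: x rightward, y downward (image convention), origin at the arena's
top-left corner.  Each tube ROI is an axis-aligned rectangle in template
coordinates with a designated food end (one of the two short sides).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RoiSpec",
    "ArenaTemplate",
    "sleep_arena_template",
    "single_tube_template",
    "triangle_area",
]


def triangle_area(points: np.ndarray) -> float:
    """Unsigned area of the triangle spanned by three 2-D points."""
    p = np.asarray(points, dtype=float)
    if p.shape != (3, 2):
        raise ValueError(f"expected 3 points, got shape {p.shape}")
    u, v = p[1] - p[0], p[2] - p[0]
    return 0.5 * abs(u[0] * v[1] - u[1] * v[0])


@dataclass(frozen=True)
class RoiSpec:
    """One tube rectangle in template mm coordinates.

    ``rect`` is (x0, y0, x1, y1) with x0 < x1 and y0 < y1.  ``food_end`` names
    the short side holding the food plug: ``"left"`` (x0 side) or ``"right"``
    (x1 side) for horizontal tubes, ``"top"``/``"bottom"`` for vertical ones.
    """

    index: int
    rect: tuple[float, float, float, float]
    food_end: str = "left"

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate ROI rect {self.rect}")
        if self.food_end not in ("left", "right", "top", "bottom"):
            raise ValueError(f"unknown food_end {self.food_end!r}")

    @property
    def corners_mm(self) -> np.ndarray:
        """4x2 corner array, ordered (x0,y0), (x1,y0), (x1,y1), (x0,y1)."""
        x0, y0, x1, y1 = self.rect
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)

    @property
    def length_mm(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) if self.food_end in ("left", "right") else (y1 - y0)

    @property
    def food_end_center_mm(self) -> np.ndarray:
        x0, y0, x1, y1 = self.rect
        centers = {
            "left": ((x0, (y0 + y1) / 2)),
            "right": ((x1, (y0 + y1) / 2)),
            "top": (((x0 + x1) / 2, y0)),
            "bottom": (((x0 + x1) / 2, y1)),
        }
        return np.array(centers[self.food_end], dtype=float)

    @property
    def tube_axis_mm(self) -> np.ndarray:
        """Unit vector pointing from the food end toward the far end."""
        axes = {
            "left": (1.0, 0.0),
            "right": (-1.0, 0.0),
            "top": (0.0, 1.0),
            "bottom": (0.0, -1.0),
        }
        return np.array(axes[self.food_end], dtype=float)

    def contains_mm(self, x: float, y: float, margin: float = 0.0) -> bool:
        x0, y0, x1, y1 = self.rect
        return (x0 - margin <= x <= x1 + margin) and (y0 - margin <= y <= y1 + margin)


@dataclass
class ArenaTemplate:
    """Geometry of one behavioral arena.

    Parameters
    ----------
    fiducials_mm
        (3, 2) positions of the reference marks.  The triangle they span must
        be scalene (all side lengths distinct) so that the correspondence with
        detected marks is unambiguous, and non-degenerate.
    rois
        Tube rectangles; indices must be unique and rectangles pairwise
        disjoint.
    mm_per_px
        Nominal imaging calibration (mm per pixel), > 0.
    tube_length_mm
        Nominal tube length shared by all ROIs (used for trigger zones).
    arena_size_mm
        (width, height) of the full template, for rendering.
    fiducial_radius_mm
        Radius of the printed circular marks.
    """

    fiducials_mm: np.ndarray
    rois: list[RoiSpec]
    mm_per_px: float = 0.2
    tube_length_mm: float = 25.0
    arena_size_mm: tuple[float, float] = (70.0, 70.0)
    fiducial_radius_mm: float = 2.0

    def __post_init__(self) -> None:
        self.fiducials_mm = np.asarray(self.fiducials_mm, dtype=float)
        if self.fiducials_mm.shape != (3, 2):
            raise ValueError("an arena template needs exactly 3 fiducial marks")
        if triangle_area(self.fiducials_mm) < 1.0:
            raise ValueError("fiducial marks are (nearly) collinear")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        indices = [r.index for r in self.rois]
        if len(set(indices)) != len(indices):
            raise ValueError("ROI indices must be unique")
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        for i, a in enumerate(self.rois):
            ax0, ay0, ax1, ay1 = a.rect
            for b in self.rois[i + 1 :]:
                bx0, by0, bx1, by1 = b.rect
                if ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1:
                    raise ValueError(f"ROIs {a.index} and {b.index} overlap")

    # --- calibration helpers -------------------------------------------------
    def mm_to_px(self, points_mm: np.ndarray) -> np.ndarray:
        return np.asarray(points_mm, dtype=float) / self.mm_per_px

    @property
    def frame_shape(self) -> tuple[int, int]:
        w, h = self.arena_size_mm
        return (int(round(h / self.mm_per_px)), int(round(w / self.mm_per_px)))

    def roi_by_index(self, index: int) -> RoiSpec:
        for r in self.rois:
            if r.index == index:
                return r
        raise KeyError(index)

    # --- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "fiducials_mm": self.fiducials_mm.tolist(),
            "rois_mm": [
                {"index": r.index, "rect": list(r.rect), "food_end": r.food_end}
                for r in self.rois
            ],
            "mm_per_px": self.mm_per_px,
            "tube_length_mm": self.tube_length_mm,
            "arena_size_mm": list(self.arena_size_mm),
            "fiducial_radius_mm": self.fiducial_radius_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaTemplate":
        return cls(
            fiducials_mm=np.asarray(d["fiducials_mm"], dtype=float),
            rois=[
                RoiSpec(index=r["index"], rect=tuple(r["rect"]), food_end=r.get("food_end", "left"))
                for r in d["rois_mm"]
            ],
            mm_per_px=float(d["mm_per_px"]),
            tube_length_mm=float(d["tube_length_mm"]),
            arena_size_mm=tuple(d.get("arena_size_mm", (70.0, 70.0))),
            fiducial_radius_mm=float(d.get("fiducial_radius_mm", 2.0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ArenaTemplate":
        return cls.from_dict(json.loads(Path(path).read_text()))



def sleep_arena_template(n_tubes: int = 20, mm_per_px: float = 0.2) -> ArenaTemplate:
    """The 20-tube sleep arena: two columns of horizontal tubes.

    Tubes are 25 mm x 4 mm on a 6 mm vertical pitch; the left column has food
    at its left (outer) end, the right column at its right end.  The three
    fiducials sit near the arena corners and form a deliberately scalene
    triangle so detected/template correspondence is unique.
    """
    if n_tubes % 2 != 0:
        raise ValueError("sleep arena lodges tubes in two equal columns")
    per_col = n_tubes // 2
    tube_len, tube_w, pitch = 25.0, 4.0, 6.0
    y0 = 8.0
    rois: list[RoiSpec] = []
    for i in range(per_col):
        y = y0 + i * pitch
        rois.append(RoiSpec(index=i, rect=(3.0, y, 3.0 + tube_len, y + tube_w), food_end="left"))
    for i in range(per_col):
        y = y0 + i * pitch
        rois.append(
            RoiSpec(
                index=per_col + i,
                rect=(42.0, y, 42.0 + tube_len, y + tube_w),
                food_end="right",
            )
        )
    height = y0 + per_col * pitch + 4.0
    fiducials = np.array([[4.0, 5.0], [66.0, 3.5], [35.5, height - 3.5]])
    return ArenaTemplate(
        fiducials_mm=fiducials,
        rois=rois,
        mm_per_px=mm_per_px,
        tube_length_mm=tube_len,
        arena_size_mm=(70.0, height),
        fiducial_radius_mm=2.0,
    )


def single_tube_template(mm_per_px: float = 0.1, tube_length_mm: float = 25.0) -> ArenaTemplate:
    """A one-tube arena used for tracking fixtures at high calibration."""
    tube_w = 4.0
    rect = (3.0, 3.0, 3.0 + tube_length_mm, 3.0 + tube_w)
    w = tube_length_mm + 6.0
    h = 12.0
    fiducials = np.array([[1.5, 1.5], [w - 1.5, 2.1], [w / 2 - 3.0, h - 1.8]])
    return ArenaTemplate(
        fiducials_mm=fiducials,
        rois=[RoiSpec(index=0, rect=rect, food_end="left")],
        mm_per_px=mm_per_px,
        tube_length_mm=tube_length_mm,
        arena_size_mm=(w, h),
        fiducial_radius_mm=1.0,
    )
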