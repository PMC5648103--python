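"""ROI registration from the arena's three printed reference marks.

Every arena carries 3 dark circular fiducials at known template positions.
Registration finds them in the first frame, solves the exact affine map from
template mm coordinates to image pixels (3 point pairs determine a 2x3 affine
uniquely), and projects the template's tube rectangles into the image.  The
template triangle must be scalene: corresponding points are identified by
ordering each triangle's vertices by the length of the opposite side, which
is invariant to rotation, translation and scale.

Registration is performed once per experiment and held fixed — the arena
locks into the machine and does not move.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .arena import ArenaTemplate, triangle_area

__all__ = [
    "NoFiducialsError",
    "AmbiguousFiducialsError",
    "DegenerateGeometryError",
    "FiducialSet",
    "AffineTransform",
    "ROI",
    "detect_fiducials",
    "fit_arena_transform",
    "build_rois",
    "register_arena",
]


class NoFiducialsError(RuntimeError):
    """Fewer than 3 fiducial candidates were found."""


class AmbiguousFiducialsError(RuntimeError):
    """More than 3 candidates, none of whose triplets match the template."""


class DegenerateGeometryError(RuntimeError):
    """Fiducial points are collinear; the affine map is underdetermined."""


@dataclass
class FiducialSet:
    """Three detected mark centers (px) with their detection scores."""

    points: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.points.shape != (3, 2):
            raise ValueError("a fiducial set holds exactly 3 points")
        d = [np.linalg.norm(self.points[i] - self.points[j]) for i, j in combinations(range(3), 2)]
        if min(d) <= 0:
            raise ValueError("fiducial points must be distinct")


@dataclass
class AffineTransform:
    """2x3 matrix mapping template mm coordinates to image px."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise DegenerateGeometryError("affine linear part is singular")

    def apply(self, pts_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return p @ self.matrix[:, :2].T + self.matrix[:, 2]

    @property
    def scale_px_per_mm(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:, :2]))))

    @property
    def rotation_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))


@dataclass
class ROI:
    """A registered tube region in image coordinates."""

    index: int
    corners_px: np.ndarray          # 4x2, ordered as the template rect corners
    mm_per_px: float
    food_end: str
    food_end_center_px: np.ndarray
    tube_axis_px: np.ndarray        # unit vector, food end -> far end
    tube_length_mm: float
    out_of_bounds: bool = False

    def __post_init__(self) -> None:
        self.corners_px = np.asarray(self.corners_px, dtype=float)
        if self.corners_px.shape != (4, 2):
            raise ValueError("ROI needs 4 corners")
        if abs(_polygon_area(self.corners_px)) < 1.0:
            raise ValueError("degenerate ROI polygon")

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Integer (x0, y0, x1, y1) bounding box, half-open."""
        x0 = int(np.floor(self.corners_px[:, 0].min()))
        y0 = int(np.floor(self.corners_px[:, 1].min()))
        x1 = int(np.ceil(self.corners_px[:, 0].max())) + 1
        y1 = int(np.ceil(self.corners_px[:, 1].max())) + 1
        return x0, y0, x1, y1

    def crop(self, frame: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.bbox
        h, w = frame.shape
        return frame[max(y0, 0) : min(y1, h), max(x0, 0) : min(x1, w)]

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean in-polygon mask over this ROI's crop window."""
        from skimage.draw import polygon

        x0, y0, x1, y1 = self.bbox
        h = min(y1, frame_shape[0]) - max(y0, 0)
        w = min(x1, frame_shape[1]) - max(x0, 0)
        m = np.zeros((h, w), dtype=bool)
        rr, cc = polygon(
            self.corners_px[:, 1] - max(y0, 0),
            self.corners_px[:, 0] - max(x0, 0),
            shape=m.shape,
        )
        m[rr, cc] = True
        return m

    def x_mm_from_food(self, point_global_px: np.ndarray) -> float:
        d = np.asarray(point_global_px, dtype=float) - self.food_end_center_px
        return float(np.dot(d, self.tube_axis_px) * self.mm_per_px)


def _polygon_area(corners: np.ndarray) -> float:
    x, y = corners[:, 0], corners[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# detection


def _refined_centroid(frame: np.ndarray, prop, pad: int = 3) -> np.ndarray:
    """Darkness-weighted centroid over the padded bounding box (sub-px)."""
    minr, minc, maxr, maxc = prop.bbox
    r0, c0 = max(minr - pad, 0), max(minc - pad, 0)
    r1, c1 = min(maxr + pad, frame.shape[0]), min(maxc + pad, frame.shape[1])
    win = frame[r0:r1, c0:c1].astype(float)
    bg = float(np.median(frame))
    w = np.clip(bg - win, 0.0, None)
    total = w.sum()
    if total <= 0:
        cy, cx = prop.centroid
        return np.array([cx, cy])
    ys, xs = np.mgrid[r0:r1, c0:c1]
    return np.array([(xs * w).sum() / total, (ys * w).sum() / total])


def detect_fiducials(
    frame: np.ndarray,
    expected_radius_px: float,
    template_triangle_mm: np.ndarray | None = None,
    dark_threshold: float | None = None,
    min_circularity: float = 0.6,
    side_ratio_tol: float = 0.08,
) -> FiducialSet:
    """Find the 3 circular reference marks in a grayscale frame.

    Dark connected components are scored by circularity (4*pi*A / P^2) and by
    how closely their equivalent radius matches ``expected_radius_px`` (within
    +/-50%).  With more than 3 candidates, the triplet whose side-length
    ratios best match the template triangle is chosen (brute force over all
    triplets); without a template triangle the 3 highest-scoring candidates
    are returned.
    """
    if frame.ndim != 2:
        raise ValueError("fiducial detection expects a single-channel frame")
    img = frame.astype(float)
    if dark_threshold is None:
        # marks are far darker than the backlit background; halfway is robust
        dark_threshold = 0.5 * (img.min() + np.median(img))
    mask = img < dark_threshold
    labels = sk_label(mask, connectivity=2)
    candidates = []
    for prop in regionprops(labels):
        r_eq = np.sqrt(prop.area / np.pi)
        if not (0.5 * expected_radius_px <= r_eq <= 1.5 * expected_radius_px):
            continue
        perim = max(prop.perimeter, 1e-9)
        circ = min(4 * np.pi * prop.area / perim**2, 1.0)
        if circ < min_circularity:
            continue
        score = circ - abs(r_eq - expected_radius_px) / expected_radius_px
        candidates.append((score, _refined_centroid(frame, prop)))
    if len(candidates) < 3:
        raise NoFiducialsError(f"found {len(candidates)} fiducial candidates, need 3")
    candidates.sort(key=lambda c: -c[0])
    if len(candidates) == 3 or template_triangle_mm is None:
        chosen = candidates[:3]
    else:
        ref = _sorted_side_ratios(np.asarray(template_triangle_mm, dtype=float))
        best, best_mismatch = None, np.inf
        for trip in combinations(candidates, 3):
            pts = np.array([c[1] for c in trip])
            if triangle_area(pts) < 1.0:
                continue
            mism = float(np.abs(_sorted_side_ratios(pts) - ref).max())
            if mism < best_mismatch:
                best, best_mismatch = trip, mism
        if best is None or best_mismatch > side_ratio_tol:
            raise AmbiguousFiducialsError(
                f"{len(candidates)} candidates; best triangle mismatch {best_mismatch:.3f} "
                f"exceeds tolerance {side_ratio_tol}"
            )
        chosen = list(best)
    pts = np.array([c[1] for c in chosen])
    if triangle_area(pts) < 1.0:
        raise DegenerateGeometryError("detected fiducials are (nearly) collinear")
    return FiducialSet(points=pts, scores=np.array([c[0] for c in chosen]))


def _side_lengths(pts: np.ndarray) -> np.ndarray:
    """Side lengths opposite each vertex: s[i] = |p[(i+1)] - p[(i+2)]|."""
    return np.array(
        [np.linalg.norm(pts[(i + 1) % 3] - pts[(i + 2) % 3]) for i in range(3)]
    )


def _sorted_side_ratios(pts: np.ndarray) -> np.ndarray:
    s = np.sort(_side_lengths(pts))
    return s / s[-1]


def _canonical_order(pts: np.ndarray) -> np.ndarray:
    """Vertices ordered by the length of the side opposite each vertex."""
    return np.argsort(_side_lengths(pts))


# ---------------------------------------------------------------------------
# transform fitting


def fit_arena_transform(detected: FiducialSet, template: ArenaTemplate) -> AffineTransform:
    """Exact affine from the 3-point template-to-image correspondence.

    Correspondence comes from sorting both triangles' vertices by opposite
    side length (requires a scalene template triangle).  The resulting system
    is square, so the solution interpolates the points with zero residual.
    """
    src = np.asarray(template.fiducials_mm, dtype=float)
    dst = np.asarray(detected.points, dtype=float)
    if triangle_area(src) < 1e-9 or triangle_area(dst) < 1e-9:
        raise DegenerateGeometryError("collinear fiducials cannot anchor an affine map")
    if np.min(np.diff(np.sort(_side_lengths(src)) / np.max(_side_lengths(src)))) < 0.01:
        raise DegenerateGeometryError(
            "template fiducial triangle is not scalene enough for unambiguous matching"
        )
    src = src[_canonical_order(src)]
    dst = dst[_canonical_order(dst)]
    # solve [x_mm y_mm 1] @ M.T = [x_px y_px] exactly
    G = np.hstack([src, np.ones((3, 1))])
    sol = np.linalg.solve(G, dst)  # 3x2
    return AffineTransform(matrix=sol.T)


def build_rois(
    template: ArenaTemplate,
    transform: AffineTransform,
    frame_shape: tuple[int, int] | None = None,
) -> list[ROI]:
    """Project every template tube into image coordinates.

    ``mm_per_px`` is recomputed from the fitted transform's scale rather than
    taken from the template, so a camera mounted nearer or farther than
    nominal still yields calibrated positions.  ROIs that land (partly)
    outside the frame are flagged, not dropped.
    """
    mm_per_px = 1.0 / transform.scale_px_per_mm
    rois = []
    for spec in template.rois:
        corners = transform.apply(spec.corners_mm)
        food_center = transform.apply([spec.food_end_center_mm])[0]
        axis = transform.matrix[:, :2] @ spec.tube_axis_mm
        axis = axis / np.linalg.norm(axis)
        oob = False
        if frame_shape is not None:
            h, w = frame_shape
            oob = bool(
                (corners[:, 0] < 0).any()
                or (corners[:, 1] < 0).any()
                or (corners[:, 0] > w).any()
                or (corners[:, 1] > h).any()
            )
        rois.append(
            ROI(
                index=spec.index,
                corners_px=corners,
                mm_per_px=mm_per_px,
                food_end=spec.food_end,
                food_end_center_px=food_center,
                tube_axis_px=axis,
                tube_length_mm=spec.length_mm,
                out_of_bounds=oob,
            )
        )
    return rois


def register_arena(frame: np.ndarray, template: ArenaTemplate) -> tuple[AffineTransform, list[ROI]]:
    """Detect fiducials, fit the transform, and build ROIs in one call."""
    expected_r = template.fiducial_radius_mm / template.mm_per_px
    detected = detect_fiducials(
        frame, expected_radius_px=expected_r, template_triangle_mm=template.fiducials_mm
    )
    transform = fit_arena_transform(detected, template)
    return transform, build_rois(template, transform, frame_shape=frame.shape)
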