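"""Per-ROI adaptive background subtraction tracking.

The default tracking mode maintains a per-ROI background image and segments
the fly as the largest over-threshold region of the absolute difference
between the current crop and the background.  The background is initialized
as the per-pixel median of the first frames (which excludes the fly wherever
it is present in fewer than half of them) and then updated with a slow
exponential filter applied *only outside the detected blob* — a parked fly is
therefore never absorbed into the background, which naive running-average
updates are prone to do during long sleep bouts.

The fly's centroid, ellipse axes and orientation come from intensity-weighted
image moments of the difference blob.  Orientation is reported modulo 180
degrees; second moments cannot distinguish head from tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from scipy import ndimage as ndi

from .core import FrameSequence, TrackPoint, Trajectory
from .registration import ROI

__all__ = [
    "NoAnimalFoundError",
    "TrackerParams",
    "BackgroundModel",
    "Blob",
    "init_background",
    "update_background",
    "segment_foreground",
    "extract_track_point",
    "track_roi",
]


class NoAnimalFoundError(RuntimeError):
    """No blob was ever detected within the grace period."""


@dataclass(frozen=True)
class TrackerParams:
    """Tunable tracking parameters.

    alpha
        Background learning rate per processed frame (0 freezes the model,
        1 replaces it); default 0.05 adapts to slow illumination drift over
        ~20 frames while staying robust to brief occlusions.
    n_init
        Number of initial frames whose per-pixel median seeds the background.
    threshold
        Absolute-difference threshold; None selects it by Otsu's method on
        the first <= 50 difference images, clipped to [20, 120].
    min_area_frac
        Minimum blob area as a fraction of the nominal fly body area
        (pi * 1.25 mm * 0.5 mm); suppresses noise specks.
    n_grace
        Frames allowed before the first detection must have happened.
    dilate_px
        Dilation radius of the blob mask excluded from background updates.
    """

    alpha: float = 0.05
    n_init: int = 5
    threshold: float | None = None
    min_area_frac: float = 0.3
    n_grace: int = 50
    dilate_px: int = 3

    def min_area_px(self, mm_per_px: float) -> float:
        body_area_mm2 = np.pi * 1.25 * 0.5
        return self.min_area_frac * body_area_mm2 / mm_per_px**2


@dataclass
class BackgroundModel:
    """Per-pixel running background estimate for one ROI crop."""

    image: np.ndarray
    alpha: float
    frame_count: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("learning rate must lie in [0, 1]")


@dataclass(frozen=True)
class Blob:
    """One segmented foreground component with moment-derived ellipse."""

    area: float
    centroid: tuple[float, float]  # (x, y) in crop px
    w: float                       # major full axis, px
    h: float                       # minor full axis, px
    phi: float                     # degrees in [0, 180)
    mask_indices: tuple = field(repr=False, default=())


def _crop_stack(frames: FrameSequence, roi: ROI, n: int) -> np.ndarray:
    crops = [roi.crop(f) for _, f in list(frames)[:n]]
    return np.stack(crops).astype(float)


def init_background(frames: FrameSequence, roi: ROI, n_init: int, alpha: float = 0.05) -> BackgroundModel:
    """Seed the background with the per-pixel median of the first crops."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    stack = _crop_stack(frames, roi, min(n_init, len(frames)))
    return BackgroundModel(image=np.median(stack, axis=0), alpha=alpha, frame_count=len(stack))


def update_background(
    model: BackgroundModel, frame_crop: np.ndarray, exclude_mask: np.ndarray | None = None
) -> BackgroundModel:
    """Selective exponential update: skip pixels under the detected blob."""
    crop = np.asarray(frame_crop, dtype=float)
    if crop.shape != model.image.shape:
        raise ValueError(f"crop shape {crop.shape} != model shape {model.image.shape}")
    new = (1.0 - model.alpha) * model.image + model.alpha * crop
    if exclude_mask is not None:
        new = np.where(exclude_mask, model.image, new)
    return BackgroundModel(image=new, alpha=model.alpha, frame_count=model.frame_count + 1)


def _ellipse_from_moments(ys: np.ndarray, xs: np.ndarray, wts: np.ndarray):
    total = wts.sum()
    cx = float((xs * wts).sum() / total)
    cy = float((ys * wts).sum() / total)
    dx, dy = xs - cx, ys - cy
    # +1/12 is the variance of a unit pixel, regularizing 1-px-thin blobs
    cxx = float((wts * dx * dx).sum() / total) + 1.0 / 12.0
    cyy = float((wts * dy * dy).sum() / total) + 1.0 / 12.0
    cxy = float((wts * dx * dy).sum() / total)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    l2, l1 = float(evals[0]), float(evals[1])
    major = evecs[:, 1]
    w = 4.0 * np.sqrt(max(l1, 1e-9))
    h = 4.0 * np.sqrt(max(l2, 1e-9))
    phi = float(np.degrees(np.arctan2(major[1], major[0])) % 180.0)
    return (cx, cy), w, h, phi


def segment_foreground(
    model: BackgroundModel,
    frame_crop: np.ndarray,
    threshold: float,
    min_area_px: float,
    roi_mask: np.ndarray | None = None,
) -> list[Blob]:
    """Threshold |crop - background| and describe each sizable component."""
    crop = np.asarray(frame_crop, dtype=float)
    if crop.shape != model.image.shape:
        raise ValueError("frame crop does not match background model shape")
    # signed difference: the animal is darker than the backlit background, so
    # foreground is where the frame falls below the model; this also rejects
    # bright "ghosts" left where a previously parked fly vacated its spot
    diff = model.image - crop
    if roi_mask is not None:
        diff = np.where(roi_mask, diff, 0.0)
    binary = diff > threshold
    labels = sk_label(binary, connectivity=2)
    blobs: list[Blob] = []
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < min_area_px:
            continue
        wts = diff[ys, xs]
        centroid, w, h, phi = _ellipse_from_moments(ys, xs, wts)
        blobs.append(
            Blob(area=float(len(ys)), centroid=centroid, w=w, h=h, phi=phi, mask_indices=(ys, xs))
        )
    return blobs


def extract_track_point(
    blobs: list[Blob], prev: TrackPoint | None, t: float, roi: ROI, crop_origin: tuple[float, float]
) -> TrackPoint:
    """Turn a blob set into the frame's track point.

    With several blobs the one nearest the previous position wins (largest
    first when there is no history).  With none, the previous position is
    carried forward and flagged as inferred so downstream velocity never
    manufactures motion from occlusion gaps.
    """
    if prev is not None and t <= prev.t:
        raise ValueError("track point times must increase")
    if not blobs:
        if prev is None:
            raise NoAnimalFoundError("no blob and no previous position")
        return replace(prev, t=t, is_inferred=True)
    if prev is None:
        blob = max(blobs, key=lambda b: b.area)
    else:
        blob = min(blobs, key=lambda b: (b.centroid[0] - prev.x) ** 2 + (b.centroid[1] - prev.y) ** 2)
    gx = blob.centroid[0] + crop_origin[0]
    gy = blob.centroid[1] + crop_origin[1]
    return TrackPoint(
        t=t,
        x=blob.centroid[0],
        y=blob.centroid[1],
        x_mm=roi.x_mm_from_food((gx, gy)),
        w=max(blob.w, blob.h),
        h=min(blob.w, blob.h),
        phi=blob.phi,
        is_inferred=False,
    )


def _remove_static_animal(image: np.ndarray, min_area_px: float) -> np.ndarray:
    """Inpaint a fly-sized dark blob out of an initial background estimate.

    If the fly never moved during the init frames, the per-pixel median still
    contains it; left in place it would both hide the fly (zero difference)
    and later seed a persistent ghost.  Strongly dark, sufficiently large
    components are replaced by the median of the remaining pixels.
    """
    bg = float(np.median(image))
    lo = float(image.min())
    if bg - lo < 60.0:  # no high-contrast object present
        return image
    dark = image < bg - 0.5 * (bg - lo)
    labels = sk_label(dark, connectivity=2)
    fill = np.zeros_like(dark)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() >= min_area_px:
            fill |= comp
    if not fill.any():
        return image
    fill = ndi.binary_dilation(fill, iterations=2)
    out = image.copy()
    out[fill] = np.median(image[~fill])
    return out


def _auto_threshold(frames: FrameSequence, roi: ROI, model: BackgroundModel, roi_mask: np.ndarray) -> float:
    n = min(50, len(frames))
    diffs = []
    for _, f in list(frames)[:n]:
        d = model.image - roi.crop(f).astype(float)
        diffs.append(np.clip(d[roi_mask], 0.0, None))
    vals = np.concatenate(diffs)
    try:
        thr = float(threshold_otsu(vals))
    except ValueError:  # constant image
        thr = 20.0
    return float(np.clip(thr, 20.0, 120.0))


def track_roi(frames: FrameSequence, roi: ROI, params: TrackerParams = TrackerParams()) -> Trajectory:
    """Track the single fly in one registered ROI across a frame sequence.

    Returns one track point per frame with input timestamps preserved.  If no
    blob is found within the first ``n_grace`` frames the ROI is declared
    empty.  Frames before the first detection are backfilled from it (marked
    inferred) so the trajectory covers every processed frame.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    x0, y0, _, _ = roi.bbox
    crop_origin = (max(x0, 0), max(y0, 0))
    roi_mask = roi.mask(frames.shape)
    model = init_background(frames, roi, params.n_init, alpha=params.alpha)
    min_area = params.min_area_px(roi.mm_per_px)
    model.image = _remove_static_animal(model.image, min_area)
    threshold = params.threshold if params.threshold is not None else _auto_threshold(frames, roi, model, roi_mask)

    points: list[TrackPoint] = []
    prev: TrackPoint | None = None
    struct = ndi.generate_binary_structure(2, 2)
    for i, (t, frame) in enumerate(frames):
        crop = roi.crop(frame).astype(float)
        blobs = segment_foreground(model, crop, threshold, min_area, roi_mask)
        try:
            pt = extract_track_point(blobs, prev, t, roi, crop_origin)
        except NoAnimalFoundError:
            if i + 1 >= params.n_grace:
                raise NoAnimalFoundError(
                    f"ROI {roi.index}: no animal detected in the first {params.n_grace} frames"
                )
            pt = None
        if pt is not None:
            if prev is None and points == [] and i > 0:
                # backfill the pre-detection frames at the first seen position
                back = [
                    replace(pt, t=float(frames.timestamps[j]), is_inferred=True) for j in range(i)
                ]
                points.extend(back)
            points.append(pt)
            prev = pt
        exclude = None
        if blobs:
            m = np.zeros_like(model.image, dtype=bool)
            for b in blobs:
                m[b.mask_indices] = True
            exclude = ndi.binary_dilation(m, structure=struct, iterations=params.dilate_px)
        model = update_background(model, crop, exclude)
    if not points:
        raise NoAnimalFoundError(f"ROI {roi.index}: no animal detected")
    return Trajectory.from_points(points, roi.index, roi.mm_per_px, crop_origin)
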