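"""Synthetic arena videos with exact ground truth.

This module renders what an infrared-backlit tube arena looks like to the
tracker — a light background, three dark circular reference marks, and one
dark fly-sized ellipse per tube — while a three-state behavior program
(immobile / micromovement / walking) drives each virtual fly.  Because the
renderer knows every centroid and every behavioral state exactly, its output
doubles as ground truth for validating registration, tracking and
classification.

The imaging model is deliberately plain: background ~200/255, tube interior
slightly brighter (backlit), fly and fiducials dark (~40/255), additive
Gaussian pixel noise clipped to [0, 255].  The fly is an anti-aliased filled
ellipse of 2.5 mm x 1 mm — one body length by one body width — at the
template calibration.

Velocities are expressed throughout in the classifier's dimensionless
"relative unit": displacement per nominal frame interval, in body lengths.
A fly moving one body length (2.5 mm) per nominal interval has corrected
velocity 1.0, the movement threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaTemplate
from .core import FrameSequence

__all__ = [
    "BODY_LENGTH_MM",
    "STATES",
    "StateKinematics",
    "DEFAULT_KINEMATICS",
    "BehaviorProgram",
    "FlyPath",
    "GroundTruth",
    "simulate_fly_trajectory",
    "render_frame",
    "generate_arena_frames",
    "default_placement",
]

BODY_LENGTH_MM = 2.5
BODY_WIDTH_MM = 1.0
STATES = ("immobile", "micromovement", "walking")

BACKGROUND_LEVEL = 200
TUBE_LEVEL = 215
DARK_LEVEL = 40


@dataclass(frozen=True)
class StateKinematics:
    """Movement-event velocity distribution for one behavioral state.

    ``mean_v`` and ``sd_v`` parameterize the corrected velocity (truncated
    normal, >= 0, relative units) of the state's characteristic movement
    events.  Defaults keep every state's event distribution >= 3 SD away from
    the classification thresholds at 1.0 and 2.5, so the generator's labels
    are recoverable by the threshold classifier by construction.

    How often events occur is part of the state's activity *pattern* (see
    :func:`simulate_fly_trajectory`): walking is sustained locomotion at the
    event velocity every frame; micromovement is in-place activity — sparse
    velocity bursts (grooming, eating, egg laying) over a quiescent baseline,
    so it accumulates little walked distance; immobile is tracking-noise
    jitter with occasional sub-threshold posture shifts.
    """

    mean_v: float
    sd_v: float


DEFAULT_KINEMATICS: dict[str, StateKinematics] = {
    "immobile": StateKinematics(0.05, 0.05),
    "micromovement": StateKinematics(1.75, 0.2),
    "walking": StateKinematics(3.5, 0.3),
}

# quiescent-baseline jitter (centroid noise scale, relative units)
BASELINE_JITTER = (0.05, 0.05)
# micromovement bursts: Poisson-like rate, with a forced burst whenever the
# gap since the last one reaches 8 s so every full 10-s window holds >= 1
MICRO_BURST_RATE_HZ = 0.15
MICRO_BURST_FORCE_S = 8.0
# immobile posture shifts stay strictly below the movement threshold
IMMOBILE_SHIFT_RATE_HZ = 0.15
IMMOBILE_SHIFT_RANGE = (0.3, 0.9)


@dataclass
class BehaviorProgram:
    """Ordered (duration_s, state) segments plus per-state kinematics."""

    segments: list[tuple[float, str]]
    kinematics: dict[str, StateKinematics] = field(
        default_factory=lambda: dict(DEFAULT_KINEMATICS)
    )

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("behavior program needs at least one segment")
        for dur, state in self.segments:
            if state not in STATES:
                raise ValueError(f"unknown behavioral state {state!r}")
            if dur <= 0:
                raise ValueError(f"segment durations must be positive, got {dur}")
        k = self.kinematics
        if not k["immobile"].mean_v < 1.0:
            raise ValueError("immobile mean velocity must sit below the movement threshold (1)")
        if not 1.0 < k["micromovement"].mean_v < 2.5:
            raise ValueError("micromovement mean velocity must sit between the thresholds (1, 2.5)")
        if not k["walking"].mean_v > 2.5:
            raise ValueError("walking mean velocity must sit above the walking threshold (2.5)")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    def state_at(self, t: float) -> str:
        """State active at time t (right-open segments; t clamped to span)."""
        acc = 0.0
        for dur, state in self.segments:
            acc += dur
            if t < acc:
                return state
        return self.segments[-1][1]

    def majority_state(self, start: float, end: float) -> str:
        """State occupying the largest share of [start, end)."""
        occupancy = dict.fromkeys(STATES, 0.0)
        acc = 0.0
        for dur, state in self.segments:
            s0, s1 = acc, acc + dur
            overlap = min(end, s1) - max(start, s0)
            if overlap > 0:
                occupancy[state] += overlap
            acc = s1
        return max(occupancy, key=occupancy.get)


@dataclass
class FlyPath:
    """Ground-truth path of one fly: mm-from-food-end positions over time."""

    t: np.ndarray
    x_mm: np.ndarray          # along the tube axis, from the food end
    y_mm: np.ndarray          # transverse offset from the tube centerline
    angle_deg: np.ndarray     # body orientation relative to the tube axis
    states: np.ndarray        # per-frame program state
    dt_nominal: float
    program: BehaviorProgram

    def window_labels(self, window_s: float = 10.0) -> pd.DataFrame:
        """Tumbling-window ground-truth labels from the driving program."""
        span = float(self.t[-1] - self.t[0])
        n_win = int(span // window_s)
        rows = []
        t0 = float(self.t[0])
        for k in range(n_win):
            start, end = t0 + k * window_s, t0 + (k + 1) * window_s
            rows.append(
                {"win_start": start, "win_end": end, "label": self.program.majority_state(start, end)}
            )
        return pd.DataFrame(rows, columns=["win_start", "win_end", "label"])


@dataclass
class GroundTruth:
    """Per-frame true positions and per-window true labels, one row per fly."""

    frames: pd.DataFrame   # frame, t, roi, x_mm, y_mm, x_px, y_px, state
    windows: pd.DataFrame  # roi, win_start, win_end, label

    def for_roi(self, roi_index: int) -> pd.DataFrame:
        return self.frames[self.frames["roi"] == roi_index].reset_index(drop=True)


def make_timestamps(
    duration_s: float, fps: float, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Frame times with intervals nominal x (1 + U(0, jitter))."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if fps <= 0:
        raise ValueError("frame rate must be positive")
    dt = 1.0 / fps
    n_guess = int(np.ceil(duration_s * fps)) + 1
    if jitter > 0:
        steps = dt * (1.0 + rng.uniform(0.0, jitter, size=2 * n_guess))
    else:
        steps = np.full(2 * n_guess, dt)
    t = np.concatenate([[0.0], np.cumsum(steps)])
    return t[t < duration_s]


def simulate_fly_trajectory(
    program: BehaviorProgram,
    tube_length_mm: float,
    seed: int,
    fps: float = 4.0,
    fps_jitter: float = 0.0,
    timestamps: np.ndarray | None = None,
    body_length_mm: float = BODY_LENGTH_MM,
    margin_mm: float = 1.3,
    transverse_halfwidth_mm: float = 0.8,
) -> FlyPath:
    """Simulate one fly's path under a three-state behavior program.

    Each step draws a corrected velocity from the active state's activity
    pattern — sustained locomotion when walking, sparse in-place bursts when
    micromoving, near-zero jitter with rare sub-threshold posture shifts when
    immobile — and converts it to an axial displacement of ``v * body_length
    * (dt / dt_nominal)`` mm, so that re-deriving corrected velocity from the
    positions recovers the drawn value.  Position is confined to
    [margin, tube_length - margin] by mirror reflection (the fly's body cannot
    leave the tube); a small mean-reverting transverse jitter keeps the fly
    near the tube centerline.
    """
    rng = np.random.default_rng(seed)
    dt_nominal = 1.0 / fps
    if timestamps is None:
        t = make_timestamps(program.total_duration, fps, fps_jitter, rng)
    else:
        t = np.asarray(timestamps, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
    n = len(t)
    lo, hi = margin_mm, tube_length_mm - margin_mm
    if hi <= lo:
        raise ValueError("tube too short for the body margin")

    x = np.empty(n)
    y = np.empty(n)
    ang = np.empty(n)
    states = np.empty(n, dtype=object)
    x[0] = rng.uniform(lo, hi)
    y[0] = 0.0
    ang[0] = 0.0
    states[0] = program.state_at(t[0])
    heading = rng.choice([-1.0, 1.0])
    last_burst = t[0]

    for i in range(1, n):
        dt_i = t[i] - t[i - 1]
        state = program.state_at(t[i])
        if state == "micromovement" and states[i - 1] != "micromovement":
            last_burst = t[i - 1]  # burst clock starts with the bout
        states[i] = state
        k = program.kinematics[state]
        if state == "walking":
            v = max(0.0, rng.normal(k.mean_v, k.sd_v))
        elif state == "micromovement":
            if (t[i] - last_burst) >= MICRO_BURST_FORCE_S or rng.random() < MICRO_BURST_RATE_HZ * dt_i:
                v = max(0.0, rng.normal(k.mean_v, k.sd_v))
                last_burst = t[i]
            else:
                v = abs(rng.normal(*BASELINE_JITTER))
        else:  # immobile
            if rng.random() < IMMOBILE_SHIFT_RATE_HZ * dt_i:
                v = rng.uniform(*IMMOBILE_SHIFT_RANGE)
            else:
                v = abs(rng.normal(*BASELINE_JITTER))
        step = v * body_length_mm * (dt_i / dt_nominal)
        if state == "walking":
            if rng.random() < 0.03:
                heading = -heading
        else:
            heading = rng.choice([-1.0, 1.0])
        xi = x[i - 1] + heading * step
        if xi < lo or xi > hi:
            # turn at the tube end: flipping the direction preserves the
            # step magnitude (a mirror reflection can cancel it near a wall)
            heading = -heading
            xi = x[i - 1] + heading * step
        while xi < lo or xi > hi:  # fallback for steps longer than the tube
            if xi < lo:
                xi = 2 * lo - xi
                heading = 1.0
            else:
                xi = 2 * hi - xi
                heading = -1.0
        x[i] = xi
        y[i] = np.clip(0.85 * y[i - 1] + rng.normal(0.0, 0.02), -transverse_halfwidth_mm, transverse_halfwidth_mm)
        if state == "walking":
            ang[i] = (0.0 if heading > 0 else 180.0) + rng.normal(0.0, 5.0)
        else:
            ang[i] = ang[i - 1] + rng.normal(0.0, 3.0)
    return FlyPath(t=t, x_mm=x, y_mm=y, angle_deg=ang, states=states, dt_nominal=dt_nominal, program=program)


# ---------------------------------------------------------------------------
# rendering


def default_placement(template: ArenaTemplate) -> np.ndarray:
    """The identity placement: template mm -> image px at nominal calibration."""
    s = 1.0 / template.mm_per_px
    return np.array([[s, 0.0, 0.0], [0.0, s, 0.0]])


def make_placement(
    template: ArenaTemplate,
    rotation_deg: float = 0.0,
    tx_px: float = 0.0,
    ty_px: float = 0.0,
    canvas_shape: tuple[int, int] | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """A similarity placement: rotate about the arena center, then translate.

    With ``canvas_shape`` given, the (possibly rotated) arena center lands at
    the canvas center plus (tx, ty); otherwise translation is relative to the
    template's own frame.  Used to emulate imperfect arena seating.
    """
    s = scale / template.mm_per_px
    th = np.radians(rotation_deg)
    R = s * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c_mm = np.array(template.arena_size_mm) / 2.0
    if canvas_shape is not None:
        center_px = np.array([canvas_shape[1] / 2.0 + tx_px, canvas_shape[0] / 2.0 + ty_px])
    else:
        center_px = c_mm / template.mm_per_px + np.array([tx_px, ty_px])
    t = center_px - R @ c_mm
    return np.hstack([R, t[:, None]])


def _apply_affine(A: np.ndarray, pts_mm: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(np.asarray(pts_mm, dtype=float))
    return p @ A[:, :2].T + A[:, 2]


def _paint(img: np.ndarray, cov: np.ndarray, ys: slice, xs: slice, value: float) -> None:
    region = img[ys, xs]
    img[ys, xs] = region * (1.0 - cov) + value * cov


def _coverage_bbox(shape, cx, cy, extent):
    y0 = max(0, int(np.floor(cy - extent - 1)))
    y1 = min(shape[0], int(np.ceil(cy + extent + 2)))
    x0 = max(0, int(np.floor(cx - extent - 1)))
    x1 = min(shape[1], int(np.ceil(cx + extent + 2)))
    return y0, y1, x0, x1


_SS = 4  # supersampling factor for anti-aliased primitives
_OFFS = (np.arange(_SS) + 0.5) / _SS - 0.5


def _add_disk(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    y0, y1, x0, x1 = _coverage_bbox(img.shape, cx, cy, r)
    if y1 <= y0 or x1 <= x0:
        return
    ys = np.arange(y0, y1)
    xs = np.arange(x0, x1)
    suby = (ys[:, None] + _OFFS[None, :]).ravel()
    subx = (xs[:, None] + _OFFS[None, :]).ravel()
    dy2 = (suby[:, None] - cy) ** 2
    dx2 = (subx[None, :] - cx) ** 2
    inside = (dy2 + dx2) <= r * r
    cov = inside.reshape(len(ys), _SS, len(xs), _SS).mean(axis=(1, 3))
    _paint(img, cov, slice(y0, y1), slice(x0, x1), value)


def _add_ellipse(
    img: np.ndarray, cx: float, cy: float, a: float, b: float, phi_deg: float, value: float
) -> None:
    """Filled anti-aliased ellipse; a, b are semi-axes in px, phi in degrees."""
    y0, y1, x0, x1 = _coverage_bbox(img.shape, cx, cy, max(a, b))
    if y1 <= y0 or x1 <= x0:
        return
    ys = np.arange(y0, y1)
    xs = np.arange(x0, x1)
    suby = (ys[:, None] + _OFFS[None, :]).ravel() - cy
    subx = (xs[:, None] + _OFFS[None, :]).ravel() - cx
    c, s = np.cos(np.radians(phi_deg)), np.sin(np.radians(phi_deg))
    # rotate into the ellipse frame
    u = subx[None, :] * c + suby[:, None] * s
    w = -subx[None, :] * s + suby[:, None] * c
    inside = (u / a) ** 2 + (w / b) ** 2 <= 1.0
    cov = inside.reshape(len(ys), _SS, len(xs), _SS).mean(axis=(1, 3))
    _paint(img, cov, slice(y0, y1), slice(x0, x1), value)


def _fill_quad(img: np.ndarray, corners_px: np.ndarray, value: float) -> None:
    from skimage.draw import polygon

    rr, cc = polygon(corners_px[:, 1], corners_px[:, 0], shape=img.shape)
    img[rr, cc] = value


def render_frame(
    template: ArenaTemplate,
    fly_states: list[tuple[int, float, float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    placement: np.ndarray | None = None,
    frame_shape: tuple[int, int] | None = None,
    extra_marks_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Render one arena frame.

    ``fly_states`` holds (roi_index, x_mm from food end, y_mm transverse,
    angle_deg relative to tube axis) per fly; positions outside the fly's ROI
    are rejected.  ``placement`` is a 2x3 affine mapping template mm to image
    px (defaults to the identity placement at template calibration).
    ``extra_marks_mm`` adds distractor dark disks (for ambiguity tests).
    """
    A = default_placement(template) if placement is None else np.asarray(placement, dtype=float)
    shape = frame_shape if frame_shape is not None else template.frame_shape
    img = np.full(shape, float(BACKGROUND_LEVEL))
    scale = float(np.sqrt(abs(np.linalg.det(A[:, :2]))))  # px per mm

    for roi in template.rois:
        _fill_quad(img, _apply_affine(A, roi.corners_mm), TUBE_LEVEL)
    for fx, fy in template.fiducials_mm:
        cx, cy = _apply_affine(A, [(fx, fy)])[0]
        _add_disk(img, cx, cy, template.fiducial_radius_mm * scale, DARK_LEVEL)
    if extra_marks_mm is not None:
        for mx, my in np.atleast_2d(extra_marks_mm):
            cx, cy = _apply_affine(A, [(mx, my)])[0]
            _add_disk(img, cx, cy, template.fiducial_radius_mm * scale, DARK_LEVEL)

    for roi_index, x_mm, y_mm, angle in fly_states or []:
        roi = template.roi_by_index(roi_index)
        pos_mm = roi.food_end_center_mm + roi.tube_axis_mm * x_mm + _perp(roi.tube_axis_mm) * y_mm
        if not roi.contains_mm(pos_mm[0], pos_mm[1]):
            raise ValueError(
                f"fly position {x_mm:.2f} mm from food end lies outside ROI {roi_index}"
            )
        cx, cy = _apply_affine(A, [pos_mm])[0]
        axis_px = A[:, :2] @ roi.tube_axis_mm
        base_deg = np.degrees(np.arctan2(axis_px[1], axis_px[0]))
        _add_ellipse(
            img,
            cx,
            cy,
            0.5 * BODY_LENGTH_MM * scale,
            0.5 * BODY_WIDTH_MM * scale,
            base_deg + angle,
            DARK_LEVEL,
        )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _perp(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def fly_px_position(
    template: ArenaTemplate, roi_index: int, x_mm: float, y_mm: float, placement: np.ndarray | None = None
) -> np.ndarray:
    """Image-px centroid the renderer will draw for the given tube position."""
    A = default_placement(template) if placement is None else placement
    roi = template.roi_by_index(roi_index)
    pos_mm = roi.food_end_center_mm + roi.tube_axis_mm * x_mm + _perp(roi.tube_axis_mm) * y_mm
    return _apply_affine(A, [pos_mm])[0]


def generate_arena_frames(
    template: ArenaTemplate,
    programs: dict[int, BehaviorProgram],
    duration_s: float,
    fps_model: tuple[float, float] = (4.0, 0.0),
    seed: int = 0,
    noise_sd: float = 2.0,
    placement: np.ndarray | None = None,
) -> tuple[FrameSequence, GroundTruth]:
    """Render a full arena sequence plus exact ground truth.

    One fly per programmed ROI.  All flies share the frame clock; the frame
    interval model is nominal x (1 + U(0, jitter)), emulating the variable
    1–5 FPS regime of real-time tracking.
    """
    fps, jitter = fps_model
    if not programs:
        raise ValueError("at least one ROI must carry a behavior program")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    root = np.random.SeedSequence(seed)
    ts_rng = np.random.default_rng(root.spawn(1)[0])
    t = make_timestamps(duration_s, fps, jitter, ts_rng)

    paths: dict[int, FlyPath] = {}
    child_seeds = root.spawn(len(programs) + 1)
    for child, (roi_index, program) in zip(child_seeds[1:], sorted(programs.items())):
        rng_seed = int(child.generate_state(1)[0] % (2**31))
        paths[roi_index] = simulate_fly_trajectory(
            program, template.tube_length_mm, rng_seed, fps=fps, timestamps=t
        )

    frames = np.empty((len(t), *template.frame_shape), dtype=np.uint8)
    gt_rows = []
    for i, ti in enumerate(t):
        fly_states = []
        for roi_index, path in paths.items():
            fly_states.append((roi_index, path.x_mm[i], path.y_mm[i], path.angle_deg[i]))
            px = fly_px_position(template, roi_index, path.x_mm[i], path.y_mm[i], placement)
            gt_rows.append(
                {
                    "frame": i,
                    "t": ti,
                    "roi": roi_index,
                    "x_mm": path.x_mm[i],
                    "y_mm": path.y_mm[i],
                    "x_px": px[0],
                    "y_px": px[1],
                    "state": path.states[i],
                }
            )
        frames[i] = render_frame(
            template, fly_states, noise_sd=noise_sd, seed=seed + 7919 * i + 1, placement=placement
        )

    win_rows = []
    for roi_index, path in paths.items():
        wl = path.window_labels()
        wl.insert(0, "roi", roi_index)
        win_rows.append(wl)
    gt = GroundTruth(
        frames=pd.DataFrame(gt_rows),
        windows=pd.concat(win_rows, ignore_index=True) if win_rows else pd.DataFrame(),
    )
    return FrameSequence(frames=frames, timestamps=t), gt
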