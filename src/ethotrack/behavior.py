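"""Windowed movement features and three-state behavior classification.

A trajectory is reduced to 10-second tumbling windows; each window's maximal
*corrected velocity* — displacement per nominal frame interval, expressed in
body lengths, hence dimensionless — decides among three states:

    immobile        max velocity < 1.0
    micromovement   1.0 <= max velocity < 2.5   (grooming, eating, egg laying)
    walking         max velocity >= 2.5

The correction multiplies raw per-step speed by (dt_nominal / dt_actual) so
that the thresholds are meaningful under the variable 1–5 FPS frame clock of
real-time tracking.  The module also carries the supporting procedures used
to validate such a classifier: majority-consensus ground truth from multiple
annotators, per-class detection accuracy, centroid discrepancy against
annotated positions, and random-forest variable-importance screening of
candidate features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory
from .synth import BODY_LENGTH_MM

__all__ = [
    "THRESHOLD_MOVE",
    "THRESHOLD_WALK",
    "compute_velocity",
    "windowed_features",
    "classify_window",
    "classify_windows",
    "rank_features",
    "consensus_labels",
    "score_classifier",
    "position_discrepancy",
]

THRESHOLD_MOVE = 1.0
THRESHOLD_WALK = 2.5
LABELS = ("immobile", "micromovement", "walking")


def compute_velocity(
    traj: Trajectory, body_length_mm: float = BODY_LENGTH_MM, dt_nominal: float = 0.25
) -> pd.DataFrame:
    """Per-step corrected velocity between consecutive *real* track points.

    Inferred (carried-forward) points are skipped entirely: displacement is
    taken between the surrounding real points, so occlusion gaps neither add
    phantom motion nor zero out true motion.  Returns columns ``t`` (step end
    time), ``v_corr`` and ``step_mm``.
    """
    df = traj.df[~traj.is_inferred]
    if len(df) < 2:
        raise ValueError("need at least 2 non-inferred points to compute velocity")
    t = df["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    xy = df[["x", "y"]].to_numpy(dtype=float) * traj.mm_per_px
    step_mm = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dt = np.diff(t)
    v_corr = (step_mm / body_length_mm) * (dt_nominal / dt)
    return pd.DataFrame({"t": t[1:], "v_corr": v_corr, "step_mm": step_mm})


def windowed_features(
    traj: Trajectory,
    window_s: float = 10.0,
    body_length_mm: float = BODY_LENGTH_MM,
    dt_nominal: float = 0.25,
) -> pd.DataFrame:
    """Tumbling-window features: max corrected velocity, cumulative distance.

    Windows tile the trajectory from its first timestamp without overlap;
    a velocity step belongs to the window containing its end time.  Windows
    with fewer than 2 real points are flagged ``missing`` (their label is
    inherited downstream).
    """
    t0 = float(traj.t[0])
    span = float(traj.t[-1] - t0)
    n_win = int(span // window_s)
    if n_win < 1:
        raise ValueError("trajectory shorter than one window")
    vel = compute_velocity(traj, body_length_mm, dt_nominal)
    idx = np.floor((vel["t"].to_numpy() - t0) / window_s).astype(int)
    real_t = traj.df.loc[~traj.is_inferred, "t"].to_numpy(dtype=float)
    inf_t = traj.df.loc[traj.is_inferred, "t"].to_numpy(dtype=float)
    rows = []
    for k in range(n_win):
        sel = idx == k
        start, end = t0 + k * window_s, t0 + (k + 1) * window_s
        n_real = int(np.sum((real_t >= start) & (real_t < end)))
        has_inf = bool(np.any((inf_t >= start) & (inf_t < end)))
        if n_real < 2 and not sel.any():
            rows.append(
                {
                    "win_start": start,
                    "win_end": end,
                    "max_velocity": np.nan,
                    "cum_distance_mm": np.nan,
                    "n_points": n_real,
                    "has_inferred": has_inf,
                    "missing": True,
                }
            )
            continue
        v = vel.loc[sel, "v_corr"]
        d = vel.loc[sel, "step_mm"]
        rows.append(
            {
                "win_start": start,
                "win_end": end,
                "max_velocity": float(v.max()) if len(v) else np.nan,
                "cum_distance_mm": float(d.sum()) if len(d) else 0.0,
                "n_points": n_real,
                "has_inferred": has_inf,
                "missing": bool(len(v) == 0),
            }
        )
    return pd.DataFrame(rows)


def classify_window(
    max_velocity: float, t_move: float = THRESHOLD_MOVE, t_walk: float = THRESHOLD_WALK
) -> str:
    """Threshold rule; boundary values are assigned upward (1.0 moves)."""
    if not np.isfinite(max_velocity):
        raise ValueError("cannot classify a window with missing features")
    if max_velocity < t_move:
        return "immobile"
    if max_velocity < t_walk:
        return "micromovement"
    return "walking"


def classify_windows(
    features: pd.DataFrame, t_move: float = THRESHOLD_MOVE, t_walk: float = THRESHOLD_WALK
) -> pd.DataFrame:
    """Label every feature window; missing windows inherit the previous label.

    Leading missing windows (no predecessor to inherit from) get no label
    (None) and are excluded from downstream scoring.
    """
    labels: list[str | None] = []
    prev: str | None = None
    for _, row in features.iterrows():
        if row["missing"]:
            labels.append(prev)
        else:
            lab = classify_window(row["max_velocity"], t_move, t_walk)
            labels.append(lab)
            prev = lab
    out = features.copy()
    out["label"] = labels
    return out


def sliding_states(
    traj: Trajectory,
    window_s: float = 10.0,
    body_length_mm: float = BODY_LENGTH_MM,
    dt_nominal: float = 0.25,
    t_move: float = THRESHOLD_MOVE,
    t_walk: float = THRESHOLD_WALK,
) -> pd.DataFrame:
    """Per-frame behavioral state from a trailing (sliding) velocity window.

    This is the real-time view the trigger engine consumes: at each track
    point, the state is classified from the maximum corrected velocity of
    the steps ending within the trailing ``window_s`` seconds.  A frame with
    no steps in its window (sequence start) reads as immobile — absence of
    evidence of motion.  Returns (t, state, x_mm).
    """
    df = traj.df[~traj.is_inferred]
    t = df["t"].to_numpy(dtype=float)
    x_mm = df["x_mm"].to_numpy(dtype=float)
    if len(df) < 2:
        return pd.DataFrame({"t": t, "state": ["immobile"] * len(t), "x_mm": x_mm})
    vel = compute_velocity(traj, body_length_mm, dt_nominal)
    vt = vel["t"].to_numpy()
    vv = vel["v_corr"].to_numpy()
    states = []
    for ti in t:
        sel = (vt > ti - window_s) & (vt <= ti)
        vmax = vv[sel].max() if sel.any() else 0.0
        states.append(classify_window(vmax, t_move, t_walk))
    return pd.DataFrame({"t": t, "state": states, "x_mm": x_mm})


def rank_features(
    feature_table: pd.DataFrame,
    labels: np.ndarray | list[str],
    seed: int,
    n_estimators: int = 200,
) -> list[tuple[str, float]]:
    """Random-forest variable importance over candidate movement features.

    Used to screen predictors in a supervised manner; deterministic under a
    fixed seed.  Returns (feature, importance) sorted by decreasing
    importance; importances are non-negative and sum to 1.
    """
    from sklearn.ensemble import RandomForestClassifier

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("feature screening needs at least 2 classes")
    X = feature_table.to_numpy(dtype=float)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=int(seed))
    rf.fit(X, y)
    pairs = sorted(
        zip(feature_table.columns, rf.feature_importances_), key=lambda p: -p[1]
    )
    return [(name, float(imp)) for name, imp in pairs]


@dataclass(frozen=True)
class ConsensusLabel:
    window_id: object
    labels: tuple[str, ...]
    consensus: str | None   # None when excluded as ambiguous

    @property
    def ambiguous(self) -> bool:
        return self.consensus is None


def consensus_labels(annotations: dict[object, list[str]]) -> list[ConsensusLabel]:
    """Strict-majority consensus across >= 3 annotators per window.

    Windows where no label reaches a strict majority are excluded as
    ambiguous rather than forced into a class.
    """
    out = []
    for wid, labs in annotations.items():
        if len(labs) < 3:
            raise ValueError(f"window {wid!r} has {len(labs)} annotations; need >= 3")
        for lab in labs:
            if lab not in LABELS:
                raise ValueError(f"unknown label {lab!r}")
        counts = pd.Series(labs).value_counts()
        consensus = counts.index[0] if counts.iloc[0] > len(labs) / 2 else None
        out.append(ConsensusLabel(window_id=wid, labels=tuple(labs), consensus=consensus))
    return out


def score_classifier(
    predicted: dict[object, str] | pd.Series, truth: list[ConsensusLabel]
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-class detection accuracy (recall) and the full confusion table.

    Ambiguous (excluded) windows are ignored.  Accuracy for class c is the
    fraction of consensus-c windows the classifier also called c.
    """
    pred = dict(predicted)
    kept = [c for c in truth if not c.ambiguous and c.window_id in pred]
    if not kept:
        raise ValueError("no unambiguous truth windows to score against")
    conf = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS))
    for c in kept:
        conf.loc[c.consensus, pred[c.window_id]] += 1
    acc = {}
    for lab in LABELS:
        n = int(conf.loc[lab].sum())
        if n > 0:
            acc[lab] = float(conf.loc[lab, lab] / n)
    return acc, conf


def position_discrepancy(
    predicted: Trajectory,
    annotated: pd.DataFrame,
    body_length_mm: float = BODY_LENGTH_MM,
    time_tol_s: float = 1e-6,
) -> dict:
    """Distance between tracked and annotated centroids, frame-matched by time.

    ``annotated`` needs columns (t, x_px, y_px) in global image coordinates.
    Returns per-frame distances in micrometres, their median, and the
    fraction of frames whose error exceeds one body length.
    """
    ann = annotated.sort_values("t").reset_index(drop=True)
    pt = predicted.df["t"].to_numpy(dtype=float)
    xy = predicted.xy_global_px
    dists_um = []
    for _, row in ann.iterrows():
        j = int(np.argmin(np.abs(pt - row["t"])))
        if abs(pt[j] - row["t"]) > time_tol_s:
            continue
        d_px = float(np.hypot(xy[j, 0] - row["x_px"], xy[j, 1] - row["y_px"]))
        dists_um.append(d_px * predicted.mm_per_px * 1000.0)
    if not dists_um:
        raise ValueError("no frames could be matched by timestamp")
    dists = np.asarray(dists_um)
    return {
        "distances_um": dists,
        "median_um": float(np.median(dists)),
        "fraction_exceeding_body_length": float(np.mean(dists > body_length_mm * 1000.0)),
        "n": int(len(dists)),
    }
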