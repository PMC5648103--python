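"""End-to-end validation studies on synthetic ground truth.

Each study regenerates its inputs from a seed, runs the relevant pipeline
stage, and measures the quantity a validation of that stage reports:
registration round-trip error, tracking discrepancy, per-class behavior
detection accuracy, feature-screening rank stability, trigger-evaluator
equivalence, closed-loop event semantics, the three-arm deprivation design,
and the statistics contracts (bootstrap coverage, rank-sum exactness, Tukey
whiskers).  The same routines back both the test suite and the
``scripts/acceptance.py`` entry point.
"""

from __future__ import annotations

import itertools
import json

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .arena import single_tube_template, sleep_arena_template
from .behavior import classify_windows, rank_features, windowed_features
from .registration import register_arena
from .sleep import bootstrap_ci, rank_sum_test, tukey_whiskers
from .synth import (
    BehaviorProgram,
    STATES,
    generate_arena_frames,
    make_placement,
    render_frame,
    simulate_fly_trajectory,
)
from .tracking import track_roi
from .triggers import (
    And,
    BehaviorIs,
    Not,
    Or,
    PositionCrossed,
    PositionWithin,
    RoiHistory,
    evaluate_trigger,
    naive_evaluate_trigger,
    run_closed_loop,
    serialize_trigger,
    sleep_deprivation_trigger,
)
from .virtualfly import run_three_arm_experiment

__all__ = [
    "registration_roundtrip_study",
    "tracking_accuracy_study",
    "classifier_recovery_study",
    "feature_screening_study",
    "trigger_oracle_study",
    "closed_loop_semantics_study",
    "deprivation_design_study",
    "bootstrap_coverage_study",
    "wilcoxon_exactness_study",
    "tukey_whisker_study",
]


def _random_program(rng: np.random.Generator, n_segments: int = 6, seg_s: float = 30.0) -> BehaviorProgram:
    segs = [(seg_s, STATES[int(rng.integers(3))]) for _ in range(n_segments)]
    return BehaviorProgram(segments=segs)


# --- registration -----------------------------------------------------------


def registration_roundtrip_study(n_placements: int = 100, seed: int = 0) -> dict:
    """Random rigid placements of the 20-tube arena: detect -> fit -> build.

    Rotations up to 10 degrees and translations up to 30 px, rendered with
    mild pixel noise.  Reports the worst per-placement RMS corner error.
    """
    tpl = sleep_arena_template()
    rng = np.random.default_rng(seed)
    canvas = (460, 450)
    rms_all = []
    for k in range(n_placements):
        A = make_placement(
            tpl,
            rotation_deg=rng.uniform(-10, 10),
            tx_px=rng.uniform(-30, 30),
            ty_px=rng.uniform(-30, 30),
            canvas_shape=canvas,
        )
        frame = render_frame(tpl, [], noise_sd=2.0, seed=int(rng.integers(2**31)), placement=A, frame_shape=canvas)
        _, rois = register_arena(frame, tpl)
        sq = []
        for r in rois:
            truth = tpl.roi_by_index(r.index).corners_mm @ A[:, :2].T + A[:, 2]
            sq.append(np.sum((r.corners_px - truth) ** 2, axis=1))
        rms_all.append(float(np.sqrt(np.mean(np.concatenate(sq)))))
    return {
        "max_rms_px": float(np.max(rms_all)),
        "mean_rms_px": float(np.mean(rms_all)),
        "n_placements": n_placements,
    }


# --- tracking ---------------------------------------------------------------


def tracking_accuracy_study(n_videos: int = 20, duration_s: float = 300.0, noise_sd: float = 5.0, seed: int = 0) -> dict:
    """Track synthetic single-fly videos at 1–5 FPS against ground truth.

    The analogue of validating the tracker against manually annotated still
    frames: distances between tracked and true centroids, in micrometres at
    a 0.1 mm/px calibration, plus the count of frames whose error exceeds
    one body length (2.5 mm).
    """
    tpl = single_tube_template()  # 0.1 mm/px
    root = np.random.SeedSequence(seed)
    dists_um = []
    for child in root.spawn(n_videos):
        rng = np.random.default_rng(child)
        fps = float(rng.uniform(1.0, 5.0))
        prog = _random_program(rng, n_segments=int(np.ceil(duration_s / 30.0)))
        vid_seed = int(child.generate_state(1)[0] % (2**31))
        seq, gt = generate_arena_frames(
            tpl, {0: prog}, duration_s, fps_model=(fps, 0.1), seed=vid_seed, noise_sd=noise_sd
        )
        _, rois = register_arena(seq.frames[0], tpl)
        traj = track_roi(seq, rois[0])
        g = gt.for_roi(0)
        xy = traj.xy_global_px
        d_px = np.hypot(xy[:, 0] - g["x_px"].to_numpy(), xy[:, 1] - g["y_px"].to_numpy())
        dists_um.append(d_px * traj.mm_per_px * 1000.0)
    d = np.concatenate(dists_um)
    return {
        "median_um": float(np.median(d)),
        "n_frames": int(len(d)),
        "n_exceeding_body_length": int(np.sum(d > 2500.0)),
        "max_um": float(d.max()),
    }


# --- classification ---------------------------------------------------------


def classifier_recovery_study(min_windows: int = 1000, seed: int = 0) -> dict:
    """Per-class detection accuracy of the threshold classifier on generator
    trajectories whose state velocity distributions sit >= 3 SD from the
    thresholds (the generator's defaults)."""
    rng = np.random.default_rng(seed)
    confusion = {s: dict.fromkeys(STATES, 0) for s in STATES}
    total = 0
    from .core import Trajectory

    while total < min_windows:
        prog = _random_program(rng, n_segments=8)
        fps = float(rng.uniform(1.0, 5.0))
        path = simulate_fly_trajectory(prog, 25.0, seed=int(rng.integers(2**31)), fps=fps)
        df = pd.DataFrame(
            {
                "t": path.t, "x": path.x_mm / 0.1, "y": path.y_mm / 0.1, "x_mm": path.x_mm,
                "w": 25.0, "h": 10.0, "phi": 0.0, "is_inferred": False,
            }
        )
        traj = Trajectory(df, 0, 0.1)
        feats = classify_windows(windowed_features(traj, dt_nominal=1.0 / fps))
        truth = path.window_labels()
        m = min(len(feats), len(truth))
        for i in range(m):
            confusion[truth["label"][i]][feats["label"][i]] += 1
        total += m
    recall = {
        s: confusion[s][s] / max(sum(confusion[s].values()), 1) for s in STATES
    }
    return {"recall": recall, "n_windows": total, "confusion": confusion}


def feature_screening_study(n_seeds: int = 10, seed: int = 0) -> dict:
    """Random-forest importance of max velocity vs cumulative distance on
    velocity-defined synthetic labels, across forest seeds."""
    rng = np.random.default_rng(seed)
    from .core import Trajectory

    feats_all, labels_all = [], []
    for _ in range(10):
        prog = _random_program(rng, n_segments=8)
        fps = float(rng.uniform(2.0, 5.0))
        path = simulate_fly_trajectory(prog, 25.0, seed=int(rng.integers(2**31)), fps=fps)
        df = pd.DataFrame(
            {
                "t": path.t, "x": path.x_mm / 0.1, "y": path.y_mm / 0.1, "x_mm": path.x_mm,
                "w": 25.0, "h": 10.0, "phi": 0.0, "is_inferred": False,
            }
        )
        feats = windowed_features(Trajectory(df, 0, 0.1), dt_nominal=1.0 / fps)
        truth = path.window_labels()
        m = min(len(feats), len(truth))
        feats_all.append(feats.iloc[:m][["max_velocity", "cum_distance_mm"]])
        labels_all.append(truth["label"].iloc[:m])
    X = pd.concat(feats_all, ignore_index=True).dropna()
    y = pd.concat(labels_all, ignore_index=True)[X.index]
    first_ranked = []
    for s in range(n_seeds):
        ranked = rank_features(X, y, seed=s)
        first_ranked.append(ranked[0][0])
    wins = sum(1 for f in first_ranked if f == "max_velocity")
    return {"max_velocity_first": wins, "n_seeds": n_seeds, "n_windows": int(len(X))}


# --- triggers ---------------------------------------------------------------

TRIGGER_LEAVES = (
    BehaviorIs("immobile", 20),
    BehaviorIs("walking", 10),
    PositionWithin(0, 5),
    PositionCrossed(12.5),
)


def enumerate_trees(leaves=TRIGGER_LEAVES, depth: int = 3) -> list:
    """All distinct predicate trees up to the given depth over the leaf set."""
    trees = {json.dumps(serialize_trigger(p), sort_keys=True): p for p in leaves}
    for _ in range(depth - 1):
        current = list(trees.values())
        for t in current:
            c = Not(t)
            trees.setdefault(json.dumps(serialize_trigger(c), sort_keys=True), c)
        for a, b in itertools.product(current, current):
            for c in (And((a, b)), Or((a, b))):
                trees.setdefault(json.dumps(serialize_trigger(c), sort_keys=True), c)
    return list(trees.values())


def trigger_oracle_study(n_steps: int = 200, n_sequences: int = 2, depth: int = 3, seed: int = 0) -> dict:
    """Exhaustive equivalence of the incremental evaluator against the
    re-scan-from-scratch oracle over all depth-limited predicate trees."""
    trees = enumerate_trees(depth=depth)
    rng = np.random.default_rng(seed)
    mismatches = 0
    n_evals = 0
    for _ in range(n_sequences):
        ts = np.arange(1.0, n_steps + 1.0)
        states = rng.choice(list(STATES), size=n_steps)
        xs = rng.choice(np.linspace(1.25, 23.75, 10), size=n_steps)
        h = RoiHistory()
        for i in range(n_steps):
            h.append(ts[i], states[i], xs[i])
            for tree in trees:
                inc = evaluate_trigger(tree, h, ts[i])
                ref = naive_evaluate_trigger(tree, ts[: i + 1], states[: i + 1], xs[: i + 1], ts[i])
                mismatches += int(inc != ref)
                n_evals += 1
    return {"mismatches": mismatches, "n_trees": len(trees), "n_evaluations": n_evals}


def closed_loop_semantics_study(duration_s: float = 3600.0, fps: float = 1.0) -> dict:
    """Permanently immobile fly, 20-s immobility trigger, 5-s mask.

    The engine's event train must equal a brute-force step-through of the
    stated semantics (fire after 20 s of continuity, suppress samples for
    5 s, restart the clock at mask end), and nothing may fall inside a mask.
    """
    ts = np.arange(1.0, duration_s + 1.0, 1.0 / fps)
    stream = pd.DataFrame({"t": ts, "state": "immobile", "x_mm": 10.0})
    events, masked = run_closed_loop(stream, sleep_deprivation_trigger(20.0), mask_s=5.0)

    fired, mask_until, clock_start = [], -np.inf, None
    for t in ts:
        if t <= mask_until:
            continue
        if clock_start is None:
            clock_start = mask_until if np.isfinite(mask_until) else t
        if t - clock_start >= 20.0:
            fired.append(t)
            mask_until = t + 5.0
            clock_start = None
    mt = masked["t"].to_numpy()
    violations = sum(
        int((((mt > e.t) & (mt <= e.t + 5.0)).any()) or
            any((o.t > e.t) and (o.t <= e.t + 5.0) for o in events))
        for e in events
    )
    return {
        "event_count": len(events),
        "oracle_count": len(fired),
        "agrees": [e.t for e in events] == fired,
        "mask_violations": int(violations),
        "n_samples": int(len(ts)),
    }


# --- deprivation design -----------------------------------------------------


def deprivation_design_study(n_seeds: int = 10, n_flies: int = 20, seed: int = 0) -> dict:
    """Repeat the three-arm closed-loop deprivation experiment across seeds.

    Counts the seeds in which each stimulated arm shows rebound sleep above
    the unstimulated mock arm (rank-sum p < 0.05), and pools stimulus counts.
    """
    root = np.random.SeedSequence(seed)
    deprived_sig = yoked_sig = 0
    p_dep, p_yok = [], []
    counts = {"deprived": [], "yoked": []}
    for child in root.spawn(n_seeds):
        s = int(child.generate_state(1)[0] % (2**31))
        res = run_three_arm_experiment(n_flies=n_flies, seed=s)
        pw = res["pairwise"].set_index(["group_a", "group_b"])["p"]
        means = res["per_fly"].groupby("group")["sleep_min"].mean()
        dep_re = pw[("deprived", "mock")] < 0.05 and means["deprived"] > means["mock"]
        yok_re = pw[("yoked", "mock")] < 0.05 and means["yoked"] > means["mock"]
        deprived_sig += int(dep_re)
        yoked_sig += int(yok_re)
        p_dep.append(float(pw[("deprived", "mock")]))
        p_yok.append(float(pw[("yoked", "mock")]))
        counts["deprived"].extend(res["stim_counts"]["deprived"].tolist())
        counts["yoked"].extend(res["stim_counts"]["yoked"].tolist())
    return {
        "n_seeds": n_seeds,
        "n_flies": n_flies,
        "deprived_rebound_seeds": deprived_sig,
        "yoked_rebound_seeds": yoked_sig,
        "median_p_deprived_vs_mock": float(np.median(p_dep)),
        "median_p_yoked_vs_mock": float(np.median(p_yok)),
        "stim_mean_deprived": float(np.mean(counts["deprived"])),
        "stim_sd_deprived": float(np.std(counts["deprived"], ddof=1)),
        "stim_mean_yoked": float(np.mean(counts["yoked"])),
        "stim_sd_yoked": float(np.std(counts["yoked"], ddof=1)),
    }


# --- statistics contracts ---------------------------------------------------


def bootstrap_coverage_study(n_reps: int = 500, n: int = 50, n_boot: int = 5000, seed: int = 0) -> dict:
    """Empirical coverage of the 95% percentile bootstrap CI of the mean on
    standard normal samples."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_reps):
        x = rng.normal(size=n)
        _, lo, hi = bootstrap_ci(x, n_boot=n_boot, seed=int(rng.integers(2**31)))
        hits += int(lo <= 0.0 <= hi)
    return {"coverage": hits / n_reps, "n_reps": n_reps, "n": n}


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    all_w = np.array([sum(c) for c in itertools.combinations(ranks, na)])
    mu = all_w.mean()
    return float(np.mean(np.abs(all_w - mu) >= abs(w_obs - mu) - 1e-12))


def wilcoxon_exactness_study(seed: int = 0) -> dict:
    """Compare the rank-sum p-value against full null enumeration, n <= 10."""
    rng = np.random.default_rng(seed)
    errs = []
    n_pairs = 0
    for na, nb in [(4, 4), (5, 7), (6, 6), (8, 8), (10, 9), (10, 10)]:
        a = rng.normal(0.0, 1.0, na)
        b = rng.normal(0.7, 1.0, nb)
        errs.append(abs(rank_sum_test(a, b) - _exact_rank_sum_p(a, b)))
        n_pairs += 1
    return {"max_abs_error": float(max(errs)), "n_pairs": n_pairs}


def tukey_whisker_study() -> dict:
    """Check the whisker rule on fixed vectors with and without outliers."""
    vectors = [
        np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100.0]),
        np.array([-50, 0, 1, 2, 3, 4, 5, 6, 7, 8.0]),
        np.linspace(0, 1, 11),
        np.array([3.0, 3.0, 3.0, 3.0]),
    ]
    violations = 0
    for v in vectors:
        lo, hi = tukey_whiskers(v)
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        in_lo = v[v >= q1 - 1.5 * iqr]
        in_hi = v[v <= q3 + 1.5 * iqr]
        if lo != in_lo.min() or hi != in_hi.max():
            violations += 1
    return {"violations": violations, "n_vectors": len(vectors)}
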