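import numpy as np
import pandas as pd
import pytest

from ethotrack.behavior import (
    classify_window,
    classify_windows,
    compute_velocity,
    consensus_labels,
    position_discrepancy,
    rank_features,
    score_classifier,
    windowed_features,
)
from ethotrack.core import Trajectory


def make_traj(t, x_mm, mm_per_px=0.1, inferred=None):
    t = np.asarray(t, dtype=float)
    x_mm = np.asarray(x_mm, dtype=float)
    inf = np.zeros(len(t), dtype=bool) if inferred is None else np.asarray(inferred)
    df = pd.DataFrame(
        {
            "t": t,
            "x": x_mm / mm_per_px,
            "y": 0.0,
            "x_mm": x_mm,
            "w": 25.0,
            "h": 10.0,
            "phi": 0.0,
            "is_inferred": inf,
        }
    )
    return Trajectory(df, 0, mm_per_px)


class TestCorrectedVelocity:
    def test_one_body_length_per_nominal_interval_is_unit(self):
        traj = make_traj([0.0, 0.25], [0.0, 2.5])
        v = compute_velocity(traj, dt_nominal=0.25)
        assert v["v_corr"].iloc[0] == pytest.approx(1.0)

    def test_zero_displacement_is_zero(self):
        traj = make_traj([0.0, 0.25], [3.0, 3.0])
        assert compute_velocity(traj, dt_nominal=0.25)["v_corr"].iloc[0] == 0.0

    def test_double_interval_halves_velocity(self):
        v1 = compute_velocity(make_traj([0.0, 0.25], [0.0, 2.5]), dt_nominal=0.25)
        v2 = compute_velocity(make_traj([0.0, 0.5], [0.0, 2.5]), dt_nominal=0.25)
        assert v2["v_corr"].iloc[0] == pytest.approx(v1["v_corr"].iloc[0] / 2.0)

    def test_inferred_points_bridge_without_phantom_motion(self):
        # position carried forward during occlusion, then resumes: velocity is
        # computed between the surrounding real points only
        t = [0.0, 0.25, 0.5, 0.75]
        x = [0.0, 1.0, 1.0, 2.0]
        traj = make_traj(t, x, inferred=[False, False, True, False])
        v = compute_velocity(traj, dt_nominal=0.25)
        assert len(v) == 2
        # the bridged step spans 0.5 s: displacement 1 mm over 2 intervals
        assert v["v_corr"].iloc[1] == pytest.approx((1.0 / 2.5) * (0.25 / 0.5))

    def test_too_few_real_points_rejected(self):
        with pytest.raises(ValueError):
            compute_velocity(make_traj([0.0], [0.0]))


class TestWindowedFeatures:
    def test_constant_velocity_window_max(self):
        t = np.arange(0, 20.25, 0.25)
        x = np.cumsum(np.full(len(t), 0.5)) # 0.5 mm per 0.25 s
        feats = windowed_features(make_traj(t, x), dt_nominal=0.25)
        assert feats["max_velocity"].iloc[0] == pytest.approx(0.2, rel=1e-6)

    def test_single_spike_dominates_max(self):
        t = np.arange(0, 10.25, 0.25)
        x = np.zeros(len(t))
        x[20:] = 5 * 2.5  # one 5-body-length jump at one step
        feats = windowed_features(make_traj(t, x), dt_nominal=0.25)
        assert feats["max_velocity"].iloc[0] == pytest.approx(5.0)

    def test_cumulative_distance_sums_displacements(self):
        t = np.arange(0, 10.25, 0.25)
        x = np.cumsum(np.full(len(t), 0.3))
        feats = windowed_features(make_traj(t, x), dt_nominal=0.25)
        # 39 steps end strictly inside the [0, 10) window (the step ending
        # exactly at t=10 belongs to the next window)
        assert feats["cum_distance_mm"].iloc[0] == pytest.approx(0.3 * 39)

    def test_empty_window_flagged_missing_and_label_inherited(self):
        # points only in windows 0 and 2; window 1 has no samples
        t = np.concatenate([np.arange(0, 10, 0.5), np.arange(20, 30, 0.5)])
        x = np.zeros(len(t))
        feats = windowed_features(make_traj(t, x), dt_nominal=0.5)
        assert bool(feats["missing"].iloc[1])
        labeled = classify_windows(feats)
        assert labeled["label"].iloc[1] == labeled["label"].iloc[0]

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            windowed_features(make_traj([0.0, 1.0], [0.0, 1.0]))


class TestThresholdClassifier:
    @pytest.mark.parametrize(
        "v,label",
        [
            (0.5, "immobile"),
            (1.7, "micromovement"),
            (3.0, "walking"),
            (1.0, "micromovement"),  # boundary assigned upward
            (2.5, "walking"),
        ],
    )
    def test_threshold_rule(self, v, label):
        assert classify_window(v) == label

    def test_missing_features_unclassifiable(self):
        with pytest.raises(ValueError):
            classify_window(float("nan"))

    def test_threshold_monotonicity(self):
        """Raising t_move only moves windows toward immobile; raising t_walk
        only from walking toward micromovement."""
        rank = {"immobile": 0, "micromovement": 1, "walking": 2}
        vs = np.linspace(0, 4, 81)
        base = [classify_window(v, 1.0, 2.5) for v in vs]
        up_move = [classify_window(v, 1.4, 2.5) for v in vs]
        up_walk = [classify_window(v, 1.0, 3.2) for v in vs]
        for b, m in zip(base, up_move):
            assert rank[m] <= rank[b]
        for b, w in zip(base, up_walk):
            assert rank[w] <= rank[b]
            # raising t_walk alone never demotes anything below micromovement
            assert w == "immobile" if b == "immobile" else w != "immobile"


class TestFeatureScreening:
    def test_separating_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 300
        labels = rng.choice(["immobile", "walking"], size=n)
        a = np.where(labels == "walking", 3.5, 0.1) + rng.normal(0, 0.1, n)
        b = rng.normal(0, 1, n)  # pure noise
        table = pd.DataFrame({"a": a, "b": b})
        ranked = rank_features(table, labels, seed=1)
        assert ranked[0][0] == "a"
        assert ranked[0][1] > 5 * ranked[1][1]

    def test_noise_features_have_comparable_importance(self):
        rng = np.random.default_rng(1)
        n = 200
        ratios = []
        for seed in range(10):
            labels = rng.choice(["immobile", "walking"], size=n)
            table = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
            imp = dict(rank_features(table, labels, seed=seed))
            ratios.append(max(imp.values()) / max(min(imp.values()), 1e-12))
        assert max(ratios) < 3.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["immobile", "walking"], size=100)
        table = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        assert rank_features(table, labels, seed=7) == rank_features(table, labels, seed=7)

    def test_single_class_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            rank_features(table, ["walking"] * 3, seed=0)


class TestConsensus:
    def test_majority_kept(self):
        (c,) = consensus_labels({0: ["walking", "walking", "micromovement"]})
        assert c.consensus == "walking" and not c.ambiguous

    def test_three_way_split_excluded(self):
        (c,) = consensus_labels({0: ["walking", "micromovement", "immobile"]})
        assert c.ambiguous

    def test_unanimous(self):
        (c,) = consensus_labels({0: ["immobile"] * 3})
        assert c.consensus == "immobile"

    def test_fewer_than_three_annotators_rejected(self):
        with pytest.raises(ValueError):
            consensus_labels({0: ["walking", "walking"]})


class TestScoring:
    def test_perfect_predictions(self):
        truth = consensus_labels(
            {i: [lab] * 3 for i, lab in enumerate(["immobile", "micromovement", "walking"])}
        )
        acc, conf = score_classifier({0: "immobile", 1: "micromovement", 2: "walking"}, truth)
        assert all(v == 1.0 for v in acc.values())
        assert int(np.trace(conf.to_numpy())) == 3

    def test_hand_built_confusion(self):
        # 100 true walking windows, 90 detected as walking -> 90% accuracy
        truth = consensus_labels({i: ["walking"] * 3 for i in range(100)})
        truth += consensus_labels({100 + i: ["immobile"] * 3 for i in range(50)})
        pred = {i: ("walking" if i < 90 else "micromovement") for i in range(100)}
        pred.update({100 + i: "immobile" for i in range(50)})
        acc, conf = score_classifier(pred, truth)
        assert acc["walking"] == pytest.approx(0.90)
        assert conf.loc["walking", "micromovement"] == 10

    def test_all_ambiguous_truth_rejected(self):
        truth = consensus_labels({0: ["walking", "micromovement", "immobile"]})
        with pytest.raises(ValueError):
            score_classifier({0: "walking"}, truth)


class TestPositionDiscrepancy:
    def test_identical_positions(self):
        traj = make_traj(np.arange(10.0), np.arange(10.0))
        ann = pd.DataFrame({"t": traj.t, "x_px": traj.xy_global_px[:, 0], "y_px": traj.xy_global_px[:, 1]})
        d = position_discrepancy(traj, ann)
        assert d["median_um"] == 0.0 and d["fraction_exceeding_body_length"] == 0.0

    def test_uniform_3px_offset_is_300um_at_0p1mm(self):
        traj = make_traj(np.arange(10.0), np.arange(10.0), mm_per_px=0.1)
        xy = traj.xy_global_px
        ann = pd.DataFrame({"t": traj.t, "x_px": xy[:, 0] + 3.0, "y_px": xy[:, 1]})
        d = position_discrepancy(traj, ann)
        assert d["median_um"] == pytest.approx(300.0)
        assert d["fraction_exceeding_body_length"] == 0.0
        assert d["n"] == 10

    def test_no_matched_frames_rejected(self):
        traj = make_traj(np.arange(10.0), np.arange(10.0))
        ann = pd.DataFrame({"t": [100.0], "x_px": [0.0], "y_px": [0.0]})
        with pytest.raises(ValueError):
            position_discrepancy(traj, ann)
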