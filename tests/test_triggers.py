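import itertools
import json

import numpy as np
import pandas as pd
import pytest

from ethotrack.triggers import (
    And,
    BehaviorIs,
    Not,
    Or,
    PositionCrossed,
    PositionWithin,
    RoiHistory,
    Schedule,
    TriggerParseError,
    evaluate_trigger,
    naive_evaluate_trigger,
    parse_trigger,
    run_closed_loop,
    serialize_trigger,
    sleep_deprivation_trigger,
    yoked_trigger,
)


def hist_from(ts, states, xs):
    h = RoiHistory()
    for t, s, x in zip(ts, states, xs):
        h.append(t, s, x)
    return h


class TestParsing:
    def test_five_minute_immobility_anywhere(self):
        pred = parse_trigger({"behavior_is": {"state": "immobile", "min_duration_s": 300}})
        assert pred == BehaviorIs("immobile", 300.0)

    def test_micromovement_near_food(self):
        spec = {
            "and": [
                {"behavior_is": {"state": "micromovement", "min_duration_s": 20}},
                {"position_within": {"min_mm": 0, "max_mm": 5}},
            ]
        }
        pred = parse_trigger(spec, tube_length_mm=25.0)
        assert pred == And((BehaviorIs("micromovement", 20.0), PositionWithin(0.0, 5.0)))

    def test_round_trip(self):
        spec = {
            "or": [
                {"not": {"behavior_is": {"state": "walking", "min_duration_s": 10}}},
                {"and": [
                    {"position_crossed": {"boundary_mm": 12.5}},
                    {"time_in": {"windows": [[0, 43200]]}},
                ]},
            ]
        }
        pred = parse_trigger(spec, 25.0)
        assert parse_trigger(json.dumps(serialize_trigger(pred)), 25.0) == pred

    @pytest.mark.parametrize(
        "bad",
        [
            {"behave": {}},
            {"behavior_is": {"state": "hopping", "min_duration_s": 5}},
            {"behavior_is": {"state": "walking", "min_duration_s": -1}},
            {"position_within": {"min_mm": 0, "max_mm": 30}},  # beyond the tube
            "not json at all {",
        ],
    )
    def test_malformed_specs_rejected(self, bad):
        with pytest.raises((TriggerParseError, KeyError)):
            parse_trigger(bad, tube_length_mm=25.0)

    def test_midline_resolves_to_half_tube(self):
        pred = parse_trigger({"position_crossed": "midline"}, tube_length_mm=25.0)
        assert pred == PositionCrossed(12.5)


class TestEvaluation:
    def test_sustained_immobility_fires(self):
        ts = np.arange(100, 126.0)
        h = hist_from(ts, ["immobile"] * len(ts), [10.0] * len(ts))
        assert evaluate_trigger(BehaviorIs("immobile", 20), h, 125.0)

    def test_continuity_broken_by_micromovement(self):
        ts = np.arange(100, 126.0)
        states = ["immobile"] * len(ts)
        states[15] = "micromovement"  # at t=115, i.e. t_now - 10
        h = hist_from(ts, states, [10.0] * len(ts))
        assert not evaluate_trigger(BehaviorIs("immobile", 20), h, 125.0)

    def test_position_zone(self):
        h = hist_from([0.0], ["walking"], [10.0])
        assert not evaluate_trigger(PositionWithin(0, 5), h, 0.0)
        h2 = hist_from([0.0], ["walking"], [3.0])
        assert evaluate_trigger(PositionWithin(0, 5), h2, 0.0)

    def test_empty_history_is_false_never_error(self):
        h = RoiHistory()
        for pred in [
            BehaviorIs("immobile", 0),
            PositionWithin(0, 5),
            PositionCrossed(12.5),
            Not(BehaviorIs("walking", 0)),
        ]:
            # Not(leaf) may be true on empty history; just require no error
            evaluate_trigger(pred, h, 0.0)
        assert not evaluate_trigger(BehaviorIs("immobile", 0), h, 0.0)

    def test_midline_crossing_semantics(self):
        y = yoked_trigger(25.0)
        h = hist_from([0, 1.0], ["walking"] * 2, [11.0, 14.0])
        assert evaluate_trigger(y, h, 1.0)
        # oscillation on one side never crosses
        xs = [1, 5, 1, 5, 1.0]
        h2 = hist_from(np.arange(5.0), ["walking"] * 5, xs)
        assert not any(
            evaluate_trigger(y, hist_from(np.arange(i + 1.0), ["walking"] * (i + 1), xs[: i + 1]), float(i))
            for i in range(5)
        )
        # exact landing on the midline then retreat on the same side: no crossing
        h3 = hist_from([0, 1.0], ["walking"] * 2, [11.0, 12.5])
        assert not evaluate_trigger(y, h3, 1.0)
        h4 = hist_from([0, 1, 2.0], ["walking"] * 3, [11.0, 12.5, 11.0])
        assert not evaluate_trigger(y, h4, 2.0)


class TestOracleEquivalence:
    LEAVES = [
        BehaviorIs("immobile", 20),
        BehaviorIs("walking", 10),
        PositionWithin(0, 5),
        PositionCrossed(12.5),
    ]

    @staticmethod
    def trees_to_depth(leaves, depth):
        trees = {json.dumps(serialize_trigger(p), sort_keys=True): p for p in leaves}
        for _ in range(depth - 1):
            current = list(trees.values())
            for t in current:
                for cand in [Not(t)]:
                    trees.setdefault(json.dumps(serialize_trigger(cand), sort_keys=True), cand)
            for a, b in itertools.product(current, current):
                for cand in (And((a, b)), Or((a, b))):
                    trees.setdefault(json.dumps(serialize_trigger(cand), sort_keys=True), cand)
        return list(trees.values())

    def test_incremental_matches_rescan_on_random_sequence(self):
        """Depth-2 predicate trees agree exactly with the re-scan oracle on a
        200-step sequence (the exhaustive depth-3 sweep runs in acceptance)."""
        rng = np.random.default_rng(5)
        n = 200
        ts = np.arange(1.0, n + 1.0)
        states = rng.choice(["immobile", "micromovement", "walking"], size=n)
        xs = rng.choice(np.linspace(1.25, 23.75, 10), size=n)
        trees = self.trees_to_depth(self.LEAVES, 2)
        h = RoiHistory()
        for i in range(n):
            h.append(ts[i], states[i], xs[i])
            for tree in trees:
                inc = evaluate_trigger(tree, h, ts[i])
                ref = naive_evaluate_trigger(tree, ts[: i + 1], states[: i + 1], xs[: i + 1], ts[i])
                assert inc == ref


class TestClosedLoop:
    def test_first_event_and_masking_window(self):
        # immobile from t=100 s, sampled at 1 FPS; 20-s trigger + 5-s mask
        ts = np.arange(100.0, 200.0)
        stream = pd.DataFrame({"t": ts, "state": "immobile", "x_mm": 10.0})
        events, masked = run_closed_loop(stream, sleep_deprivation_trigger(20.0), mask_s=5.0)
        assert events[0].t == 120.0
        inside_mask = (masked["t"] > 120.0) & (masked["t"] <= 125.0)
        assert not inside_mask.any()

    def test_event_count_matches_discrete_event_oracle(self):
        """Permanently immobile fly over 3600 s: engine count equals a
        brute-force step-through of the stated semantics (continuity clock
        restarts at mask end)."""
        ts = np.arange(1.0, 3601.0)
        stream = pd.DataFrame({"t": ts, "state": "immobile", "x_mm": 10.0})
        events, masked = run_closed_loop(stream, sleep_deprivation_trigger(20.0), mask_s=5.0)

        def oracle(ts, d=20.0, mask_s=5.0):
            fired = []
            mask_until = -np.inf
            clock_start = None
            for t in ts:
                if t <= mask_until:
                    continue
                if clock_start is None:
                    clock_start = max(t, mask_until) if np.isfinite(mask_until) else t
                    if np.isfinite(mask_until):
                        clock_start = mask_until  # clock restarts at mask end
                if t - clock_start >= d:
                    fired.append(t)
                    mask_until = t + mask_s
                    clock_start = None
            return fired

        expect = oracle(ts)
        assert [e.t for e in events] == expect
        assert len(events) == 144  # floor(3600 / (20 + 5))
        # no event or surviving sample strictly inside any mask interval
        for e in events:
            assert not (((masked["t"] > e.t) & (masked["t"] <= e.t + 5.0)).any())
            assert not any((o.t > e.t) and (o.t <= e.t + 5.0) for o in events)

    def test_schedule_limits_events(self):
        ts = np.arange(1.0, 1001.0)
        stream = pd.DataFrame({"t": ts, "state": "immobile", "x_mm": 10.0})
        sched = Schedule(windows=((500.0, 700.0),))
        events, _ = run_closed_loop(stream, sleep_deprivation_trigger(20.0), sched, mask_s=5.0)
        assert events and all(500.0 <= e.t < 700.0 for e in events)

    def test_degenerate_stream_yields_no_events(self):
        stream = pd.DataFrame({"t": [], "state": [], "x_mm": []})
        events, masked = run_closed_loop(stream, sleep_deprivation_trigger(20.0))
        assert events == [] and len(masked) == 0

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            Schedule(windows=((0.0, 10.0), (5.0, 20.0)))
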