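"""Combinatorial behavior-triggered stimulus engine.

A trigger is a boolean predicate tree over the live track of one tube:

    behavior_is(state, min_duration_s)   continuous state over the trailing
                                         interval [t_now - d, t_now]
    position_within(min_mm, max_mm)      current position, mm from the food end
    position_crossed(boundary_mm)        the most recent step strictly crossed
                                         the boundary ("midline" = tube/2)
    time_in(schedule)                    absolute experiment time in a window

combined with ``and`` / ``or`` / ``not``.  The classic sleep-deprivation
trigger is ``behavior_is(immobile, 20 s)``; its yoked control fires on
midline crossing instead, equalizing stimulus exposure while leaving sleep
intact.  After each stimulus, tracking and triggering are suspended for a
masking interval (default 5 s) to avoid motion artefacts, and the behavioral
continuity clock restarts at mask end.

Predicates are serialized to/from a small JSON grammar (see ``parse_trigger``)
so experiments are fully described by their config files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Schedule",
    "BehaviorIs",
    "PositionWithin",
    "PositionCrossed",
    "TimeIn",
    "And",
    "Or",
    "Not",
    "TriggerParseError",
    "parse_trigger",
    "serialize_trigger",
    "RoiHistory",
    "evaluate_trigger",
    "naive_evaluate_trigger",
    "StimulusEvent",
    "run_closed_loop",
    "yoked_trigger",
    "sleep_deprivation_trigger",
]


class TriggerParseError(ValueError):
    """Malformed trigger specification."""


@dataclass(frozen=True)
class Schedule:
    """Ordered, non-overlapping (start, end) arming windows, seconds."""

    windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.windows:
            if end <= start:
                raise ValueError(f"empty schedule window ({start}, {end})")
            if start < prev_end:
                raise ValueError("schedule windows must be ordered and non-overlapping")
            prev_end = end

    def contains(self, t: float) -> bool:
        return any(start <= t < end for start, end in self.windows)

    @classmethod
    def always(cls) -> "Schedule":
        return cls(windows=((-np.inf, np.inf),))


# --- predicate tree ---------------------------------------------------------


@dataclass(frozen=True)
class BehaviorIs:
    state: str
    min_duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.state not in ("immobile", "micromovement", "walking"):
            raise TriggerParseError(f"unknown behavioral state {self.state!r}")
        if self.min_duration_s < 0:
            raise TriggerParseError("min_duration_s must be >= 0")


@dataclass(frozen=True)
class PositionWithin:
    min_mm: float
    max_mm: float

    def __post_init__(self) -> None:
        if not self.min_mm < self.max_mm:
            raise TriggerParseError("position zone must have min_mm < max_mm")
        if self.min_mm < 0:
            raise TriggerParseError("position zone starts before the food end")


@dataclass(frozen=True)
class PositionCrossed:
    boundary_mm: float

    def __post_init__(self) -> None:
        if self.boundary_mm < 0:
            raise TriggerParseError("crossing boundary must be >= 0")


@dataclass(frozen=True)
class TimeIn:
    schedule: Schedule


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


@dataclass(frozen=True)
class Not:
    child: object


def parse_trigger(spec: str | dict, tube_length_mm: float | None = None):
    """Parse the JSON mini-grammar into a predicate tree.

    Grammar (one key per node)::

        {"behavior_is": {"state": "immobile", "min_duration_s": 300}}
        {"position_within": {"min_mm": 0, "max_mm": 5}}
        {"position_crossed": "midline"}            # needs tube_length_mm
        {"position_crossed": {"boundary_mm": 12.5}}
        {"time_in": {"windows": [[0, 43200]]}}
        {"and": [ ... ]}   {"or": [ ... ]}   {"not": ...}

    Zones and boundaries are validated against the tube length when known.
    """
    if isinstance(spec, str):
        try:
            spec = json.loads(spec)
        except json.JSONDecodeError as e:
            raise TriggerParseError(f"invalid JSON: {e}") from e
    if not isinstance(spec, dict) or len(spec) != 1:
        raise TriggerParseError("each trigger node must be an object with exactly one key")
    (key, body), = spec.items()
    if key == "behavior_is":
        node = BehaviorIs(state=body["state"], min_duration_s=float(body.get("min_duration_s", 0.0)))
    elif key == "position_within":
        node = PositionWithin(min_mm=float(body["min_mm"]), max_mm=float(body["max_mm"]))
        if tube_length_mm is not None and node.max_mm > tube_length_mm:
            raise TriggerParseError("position zone extends beyond the tube end")
    elif key == "position_crossed":
        if body == "midline":
            if tube_length_mm is None:
                raise TriggerParseError("'midline' requires a tube length")
            node = PositionCrossed(boundary_mm=tube_length_mm / 2.0)
        else:
            node = PositionCrossed(boundary_mm=float(body["boundary_mm"]))
        if tube_length_mm is not None and node.boundary_mm > tube_length_mm:
            raise TriggerParseError("crossing boundary beyond the tube end")
    elif key == "time_in":
        node = TimeIn(schedule=Schedule(windows=tuple(tuple(w) for w in body["windows"])))
    elif key == "and":
        node = And(children=tuple(parse_trigger(c, tube_length_mm) for c in body))
    elif key == "or":
        node = Or(children=tuple(parse_trigger(c, tube_length_mm) for c in body))
    elif key == "not":
        node = Not(child=parse_trigger(body, tube_length_mm))
    else:
        raise TriggerParseError(f"unknown trigger leaf or combinator {key!r}")
    return node


def serialize_trigger(pred) -> dict:
    if isinstance(pred, BehaviorIs):
        return {"behavior_is": {"state": pred.state, "min_duration_s": pred.min_duration_s}}
    if isinstance(pred, PositionWithin):
        return {"position_within": {"min_mm": pred.min_mm, "max_mm": pred.max_mm}}
    if isinstance(pred, PositionCrossed):
        return {"position_crossed": {"boundary_mm": pred.boundary_mm}}
    if isinstance(pred, TimeIn):
        return {"time_in": {"windows": [list(w) for w in pred.schedule.windows]}}
    if isinstance(pred, And):
        return {"and": [serialize_trigger(c) for c in pred.children]}
    if isinstance(pred, Or):
        return {"or": [serialize_trigger(c) for c in pred.children]}
    if isinstance(pred, Not):
        return {"not": serialize_trigger(pred.child)}
    raise TypeError(f"not a trigger predicate: {pred!r}")


# --- evaluation -------------------------------------------------------------


@dataclass
class RoiHistory:
    """Incrementally maintained track history for one ROI.

    Appending a sample updates the start time of the current uninterrupted
    state run in O(1), which is what makes per-frame trigger evaluation
    cheap.  ``reset_behavior_clock`` restarts the run at a given time (used
    at mask end after a stimulus).
    """

    t: list[float] = field(default_factory=list)
    state: list[str] = field(default_factory=list)
    x_mm: list[float] = field(default_factory=list)
    run_start: float | None = None
    _pending_reset: float | None = None

    def append(self, t: float, state: str, x_mm: float) -> None:
        if self.t and t <= self.t[-1]:
            raise ValueError("history timestamps must be strictly increasing")
        new_run = not self.t or state != self.state[-1]
        if new_run:
            self.run_start = t
        elif self._pending_reset is not None:
            # continuity across a mask can only be claimed from mask end onward
            self.run_start = self._pending_reset
        self._pending_reset = None
        self.t.append(float(t))
        self.state.append(state)
        self.x_mm.append(float(x_mm))

    def reset_behavior_clock(self, t_reset: float) -> None:
        self._pending_reset = float(t_reset)


def evaluate_trigger(pred, history: RoiHistory, t_now: float) -> bool:
    """Incremental predicate evaluation against the live history.

    Empty histories are never an error: every leaf needing data is simply
    false.
    """
    if isinstance(pred, BehaviorIs):
        if not history.t:
            return False
        if history.state[-1] != pred.state:
            return False
        return history.run_start is not None and history.run_start <= t_now - pred.min_duration_s
    if isinstance(pred, PositionWithin):
        if not history.t:
            return False
        return pred.min_mm <= history.x_mm[-1] <= pred.max_mm
    if isinstance(pred, PositionCrossed):
        if len(history.t) < 2:
            return False
        a = history.x_mm[-2] - pred.boundary_mm
        b = history.x_mm[-1] - pred.boundary_mm
        return (a < 0 < b) or (a > 0 > b)
    if isinstance(pred, TimeIn):
        return pred.schedule.contains(t_now)
    if isinstance(pred, And):
        return all(evaluate_trigger(c, history, t_now) for c in pred.children)
    if isinstance(pred, Or):
        return any(evaluate_trigger(c, history, t_now) for c in pred.children)
    if isinstance(pred, Not):
        return not evaluate_trigger(pred.child, history, t_now)
    raise TypeError(f"not a trigger predicate: {pred!r}")


def naive_evaluate_trigger(
    pred, ts: np.ndarray, states: np.ndarray, xs: np.ndarray, t_now: float
) -> bool:
    """Reference evaluator that re-scans the whole history from scratch.

    Semantically identical to :func:`evaluate_trigger` but O(history) per
    call; kept as the independent oracle for the incremental path.
    """
    n = len(ts)
    if isinstance(pred, BehaviorIs):
        if n == 0 or states[-1] != pred.state:
            return False
        i = n - 1
        while i > 0 and states[i - 1] == pred.state:
            i -= 1
        return ts[i] <= t_now - pred.min_duration_s
    if isinstance(pred, PositionWithin):
        return n > 0 and pred.min_mm <= xs[-1] <= pred.max_mm
    if isinstance(pred, PositionCrossed):
        if n < 2:
            return False
        a = xs[-2] - pred.boundary_mm
        b = xs[-1] - pred.boundary_mm
        return (a < 0 < b) or (a > 0 > b)
    if isinstance(pred, TimeIn):
        return pred.schedule.contains(t_now)
    if isinstance(pred, And):
        return all(naive_evaluate_trigger(c, ts, states, xs, t_now) for c in pred.children)
    if isinstance(pred, Or):
        return any(naive_evaluate_trigger(c, ts, states, xs, t_now) for c in pred.children)
    if isinstance(pred, Not):
        return not naive_evaluate_trigger(pred.child, ts, states, xs, t_now)
    raise TypeError(f"not a trigger predicate: {pred!r}")


# --- closed loop ------------------------------------------------------------


@dataclass(frozen=True)
class StimulusEvent:
    """One delivered stimulus with a snapshot of what triggered it."""

    t: float
    roi: int
    kind: str
    params: dict = field(default_factory=dict)
    snapshot: dict = field(default_factory=dict)


DEFAULT_ROTATION_PARAMS = {"angle_deg": 60.0, "duration_s": 0.12}


def run_closed_loop(
    stream: pd.DataFrame,
    trigger,
    schedule: Schedule | None = None,
    stimulus_kind: str = "rotate",
    stimulus_params: dict | None = None,
    mask_s: float = 5.0,
    roi_index: int = 0,
) -> tuple[list[StimulusEvent], pd.DataFrame]:
    """Replay a behavior-annotated track through the trigger engine.

    ``stream`` needs time-ordered columns (t, state, x_mm).  Whenever the
    trigger fires inside the armed schedule a stimulus event is emitted, and
    samples with t in (event, event + mask_s] are suppressed — tracking is
    blind during the stimulus motion artefact.  The behavior continuity clock
    restarts at mask end.  Returns the events and the masked stream.
    """
    if schedule is None:
        schedule = Schedule.always()
    if stimulus_params is None:
        stimulus_params = dict(DEFAULT_ROTATION_PARAMS) if stimulus_kind == "rotate" else {}
    hist = RoiHistory()
    events: list[StimulusEvent] = []
    kept = np.ones(len(stream), dtype=bool)
    mask_until = -np.inf
    ts = stream["t"].to_numpy(dtype=float)
    sts = stream["state"].to_numpy()
    xs = stream["x_mm"].to_numpy(dtype=float)
    for i in range(len(stream)):
        t = float(ts[i])
        if t <= mask_until:
            kept[i] = False
            continue
        hist.append(t, sts[i], xs[i])
        if schedule.contains(t) and evaluate_trigger(trigger, hist, t):
            events.append(
                StimulusEvent(
                    t=t,
                    roi=roi_index,
                    kind=stimulus_kind,
                    params=dict(stimulus_params),
                    snapshot={"state": str(sts[i]), "x_mm": float(xs[i])},
                )
            )
            mask_until = t + mask_s
            hist.reset_behavior_clock(mask_until)
    return events, stream[kept].reset_index(drop=True)


def yoked_trigger(tube_length_mm: float = 25.0) -> PositionCrossed:
    """Midline-crossing trigger for the yoked (activity-matched) control."""
    return PositionCrossed(boundary_mm=tube_length_mm / 2.0)


def sleep_deprivation_trigger(min_immobile_s: float = 20.0) -> BehaviorIs:
    """Immobility trigger used for closed-loop sleep deprivation."""
    return BehaviorIs(state="immobile", min_duration_s=min_immobile_s)


def events_to_frame(events: list[StimulusEvent]) -> pd.DataFrame:
    rows = [
        {"t": e.t, "roi": e.roi, "kind": e.kind, "params": json.dumps(e.params)}
        for e in events
    ]
    return pd.DataFrame(rows, columns=["t", "roi", "kind", "params"])
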