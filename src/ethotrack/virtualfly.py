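"""A homeostatic virtual fly and the three-arm sleep-deprivation design.

The virtual fly is a minimal two-process-style model stepped at the behavior
window resolution (10 s): a sleep-pressure variable grows while the fly is
awake, decays while it sleeps, and raises the probability of falling asleep.
Light suppresses sleep (flies sleep mostly in the dark).  Each stimulus
arouses the fly — it wakes up, walks, and its position is jolted — but does
not change the pressure itself; rebound therefore emerges mechanistically
whenever stimulation prevents sleep from discharging pressure.

Three arms reproduce the closed-loop sleep-deprivation design:

* ``deprived``  — tube rotation after 20 s of continuous immobility,
* ``yoked``     — identical rotations, but triggered by midline crossing
                  (only awake, walking flies are hit; sleep stays intact),
* ``mock``      — never stimulated.

Only the deprived arm should accumulate pressure during the stimulation
night and show rebound sleep the next morning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sleep import SleepBout, annotate_sleep, rebound_quantification
from .triggers import (
    RoiHistory,
    Schedule,
    StimulusEvent,
    evaluate_trigger,
    sleep_deprivation_trigger,
    yoked_trigger,
)

__all__ = ["VirtualFlyParams", "simulate_fly_arm", "run_three_arm_experiment"]

HOUR = 3600.0


@dataclass(frozen=True)
class VirtualFlyParams:
    """Parameters of the homeostatic virtual fly (per 10-s step).

    Pressure units are arbitrary; with the defaults an awake fly gains one
    unit per hour and sheds two per hour asleep, so a night of lost sleep
    accumulates roughly 10 units and strongly promotes morning sleep.
    """

    dt_s: float = 10.0
    tube_length_mm: float = 25.0
    pressure_gain_per_h: float = 1.0      # while awake
    pressure_decay_per_h: float = 2.0     # while asleep
    p_fall_base: float = 0.005            # baseline P(fall asleep)/step, dark
    p_fall_per_pressure: float = 0.02
    p_wake: float = 0.008                 # spontaneous P(wake)/step
    light_sleep_suppression: float = 0.3  # multiplies p_fall during light
    light_wake_boost: float = 3.0         # multiplies p_wake during light
    p_walk_awake: float = 0.4
    p_micro_awake: float = 0.4
    walk_step_mm: float = 4.0
    micro_step_mm: float = 0.3


@dataclass
class ArmResult:
    states: pd.DataFrame            # t, state, x_mm (one row per step)
    events: list[StimulusEvent]
    bouts: list[SleepBout] = field(default_factory=list)


def _reflect(x: float, lo: float, hi: float) -> float:
    while x < lo or x > hi:
        x = 2 * lo - x if x < lo else 2 * hi - x
    return x


def simulate_fly_arm(
    arm: str,
    seed: int,
    total_h: float = 27.0,
    lights_on_off_h: tuple[float, float] = (0.0, 12.0),
    stim_window_h: tuple[float, float] = (12.0, 24.0),
    mask_s: float = 5.0,
    roi_index: int = 0,
    params: VirtualFlyParams = VirtualFlyParams(),
) -> ArmResult:
    """Simulate one fly through one arm of the deprivation design.

    The day runs on a 12 h:12 h light-dark cycle starting at lights-on
    (ZT 0); stimulation is armed during ``stim_window_h`` (the first night by
    default) and sleep rebound is read out after it ends.  The closed loop —
    incremental trigger evaluation, stimulus masking, continuity-clock reset —
    is the same engine used on tracked data.
    """
    if arm not in ("deprived", "yoked", "mock"):
        raise ValueError(f"unknown arm {arm!r}")
    p = params
    rng = np.random.default_rng(seed)
    trigger = None
    if arm == "deprived":
        trigger = sleep_deprivation_trigger(20.0)
    elif arm == "yoked":
        trigger = yoked_trigger(p.tube_length_mm)
    schedule = Schedule(windows=((stim_window_h[0] * HOUR, stim_window_h[1] * HOUR),))

    n_steps = int(total_h * HOUR / p.dt_s)
    gain = p.pressure_gain_per_h * p.dt_s / HOUR
    decay = p.pressure_decay_per_h * p.dt_s / HOUR

    hist = RoiHistory()
    events: list[StimulusEvent] = []
    mask_until = -np.inf
    pressure = 0.0
    asleep = False
    aroused = False  # forced walking on the step after a stimulus
    x = float(rng.uniform(2.0, p.tube_length_mm - 2.0))
    rows = []

    for i in range(1, n_steps + 1):
        t = i * p.dt_s
        zt_h = (t / HOUR) % 24.0
        light = lights_on_off_h[0] <= zt_h < lights_on_off_h[1]

        # --- fly dynamics -------------------------------------------------
        if aroused:
            asleep = False
            state = "walking"
            aroused = False
        else:
            if asleep:
                p_wake = p.p_wake * (p.light_wake_boost if light else 1.0)
                if rng.random() < p_wake:
                    asleep = False
            else:
                p_fall = p.p_fall_base + p.p_fall_per_pressure * pressure
                if light:
                    p_fall *= p.light_sleep_suppression
                if rng.random() < min(p_fall, 0.9):
                    asleep = True
            if asleep:
                state = "immobile"
            else:
                u = rng.random()
                if u < p.p_walk_awake:
                    state = "walking"
                elif u < p.p_walk_awake + p.p_micro_awake:
                    state = "micromovement"
                else:
                    state = "immobile"
        step = {
            "walking": p.walk_step_mm * rng.normal(0.0, 1.0),
            "micromovement": p.micro_step_mm * rng.normal(0.0, 1.0),
            "immobile": 0.0,
        }[state]
        x = _reflect(x + step, 1.0, p.tube_length_mm - 1.0)
        pressure = max(0.0, pressure - decay if asleep else pressure + gain)
        rows.append({"t": t, "state": state, "x_mm": x})

        # --- closed loop --------------------------------------------------
        if t <= mask_until:
            continue
        hist.append(t, state, x)
        if trigger is not None and schedule.contains(t) and evaluate_trigger(trigger, hist, t):
            events.append(
                StimulusEvent(t=t, roi=roi_index, kind="rotate", snapshot={"state": state, "x_mm": x})
            )
            mask_until = t + mask_s
            hist.reset_behavior_clock(mask_until)
            aroused = True

    states = pd.DataFrame(rows)
    # derive sleep bouts from per-step behavior (each step = one 10-s window)
    labels = pd.DataFrame(
        {
            "win_start": states["t"] - p.dt_s,
            "win_end": states["t"],
            "label": states["state"],
        }
    )
    bouts = annotate_sleep(labels, roi=roi_index)
    return ArmResult(states=states, events=events, bouts=bouts)


def run_three_arm_experiment(
    n_flies: int = 20,
    seed: int = 0,
    total_h: float = 27.0,
    stim_window_h: tuple[float, float] = (12.0, 24.0),
    rebound_h: float = 3.0,
    params: VirtualFlyParams = VirtualFlyParams(),
) -> dict:
    """Run deprived / yoked / mock arms and quantify rebound sleep.

    Returns per-arm bout lists, stimulus events, the per-fly rebound minutes
    table, and the pairwise Wilcoxon comparisons for the first ``rebound_h``
    hours after stimulation end.
    """
    root = np.random.SeedSequence(seed)
    arms = ("deprived", "yoked", "mock")
    children = root.spawn(len(arms) * n_flies)
    results: dict[str, list[ArmResult]] = {a: [] for a in arms}
    k = 0
    for arm in arms:
        for _ in range(n_flies):
            s = int(children[k].generate_state(1)[0] % (2**31))
            results[arm].append(
                simulate_fly_arm(arm, seed=s, total_h=total_h, stim_window_h=stim_window_h, params=params)
            )
            k += 1
    window = (stim_window_h[1] * HOUR, (stim_window_h[1] + rebound_h) * HOUR)
    per_fly, pairwise = rebound_quantification(
        {arm: [r.bouts for r in results[arm]] for arm in arms}, window
    )
    stim_counts = {
        arm: np.array(
            [
                sum(1 for e in r.events if stim_window_h[0] * HOUR <= e.t < stim_window_h[1] * HOUR)
                for r in results[arm]
            ]
        )
        for arm in arms
    }
    return {
        "results": results,
        "rebound_window": window,
        "per_fly": per_fly,
        "pairwise": pairwise,
        "stim_counts": stim_counts,
    }
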