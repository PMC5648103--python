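"""Sleep annotation, binned profiles, and the supporting statistics.

Sleep is defined by the field's standard immobility criterion: any maximal
run of immobile behavior windows lasting at least 5 minutes counts as one
sleep bout (configurable).  Profiles report the fraction of each time bin
(default 30 min) covered by sleep.  Statistics follow common practice for
this kind of data: percentile bootstrap CIs over individuals (5,000
replicates, 95%), pairwise two-sided Wilcoxon rank-sum tests between groups,
and Tukey boxplot whiskers (last extreme values within +/-1.5 IQR of the
hinges).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SleepBout",
    "annotate_sleep",
    "sleep_profile",
    "sleep_seconds_in_window",
    "bootstrap_ci",
    "rank_sum_test",
    "pairwise_wilcoxon",
    "rebound_quantification",
    "count_stimuli",
    "tukey_whiskers",
]

MIN_SLEEP_S = 300.0


@dataclass(frozen=True)
class SleepBout:
    roi: int
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def annotate_sleep(
    labels: pd.DataFrame, min_sleep_s: float = MIN_SLEEP_S, roi: int = 0
) -> list[SleepBout]:
    """Merge contiguous immobile windows into sleep bouts.

    ``labels`` needs columns (win_start, win_end, label) covering contiguous
    windows.  A maximal immobile run shorter than ``min_sleep_s`` is rest,
    not sleep, and yields no bout.
    """
    bouts: list[SleepBout] = []
    run_start: float | None = None
    run_end: float | None = None
    for _, row in labels.sort_values("win_start").iterrows():
        if row["label"] == "immobile":
            if run_start is not None and np.isclose(row["win_start"], run_end):
                run_end = row["win_end"]
            else:
                if run_start is not None and run_end - run_start >= min_sleep_s:
                    bouts.append(SleepBout(roi=roi, start=run_start, end=run_end))
                run_start, run_end = row["win_start"], row["win_end"]
        else:
            if run_start is not None and run_end - run_start >= min_sleep_s:
                bouts.append(SleepBout(roi=roi, start=run_start, end=run_end))
            run_start = run_end = None
    if run_start is not None and run_end - run_start >= min_sleep_s:
        bouts.append(SleepBout(roi=roi, start=run_start, end=run_end))
    return bouts


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def sleep_profile(
    bouts: list[SleepBout], bin_s: float = 1800.0, span: tuple[float, float] = (0.0, 86400.0)
) -> pd.DataFrame:
    """Fraction of each bin spent asleep; bins tile ``span``."""
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    t0, t1 = span
    edges = np.arange(t0, t1 + bin_s / 2, bin_s)
    rows = []
    for b0, b1 in zip(edges[:-1], edges[1:]):
        covered = sum(_overlap(b.start, b.end, b0, b1) for b in bouts)
        rows.append({"bin_start": b0, "bin_end": b1, "fraction_asleep": covered / (b1 - b0)})
    return pd.DataFrame(rows)


def sleep_seconds_in_window(bouts: list[SleepBout], window: tuple[float, float]) -> float:
    return sum(_overlap(b.start, b.end, *window) for b in bouts)


def bootstrap_ci(
    values: np.ndarray, n_boot: int = 5000, level: float = 0.95, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap CI of the mean across individuals.

    ``values`` is (n_individuals,) or (n_individuals, n_bins); individuals
    (rows) are resampled with replacement.  Returns (mean, lo, hi), each
    scalar or length-n_bins.
    """
    raw = np.asarray(values, dtype=float)
    if raw.size == 0:
        raise ValueError("empty input")
    scalar = raw.ndim == 1
    v = raw[:, None] if scalar else raw
    n = v.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs at least 2 individuals")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = v[idx].mean(axis=1)  # (n_boot, n_bins)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boot_means, alpha, axis=0)
    hi = np.quantile(boot_means, 1.0 - alpha, axis=0)
    mean = v.mean(axis=0)
    if scalar:
        return float(mean[0]), float(lo[0]), float(hi[0])
    return mean, lo, hi


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def pairwise_wilcoxon(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise rank-sum tests; returns a tidy (group_a, group_b, p) table."""
    rows = [
        {"group_a": ga, "group_b": gb, "p": rank_sum_test(groups[ga], groups[gb])}
        for ga, gb in combinations(groups, 2)
    ]
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p"])


def rebound_quantification(
    group_bouts: dict[str, list[list[SleepBout]]],
    window: tuple[float, float],
    alive: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fly sleep in the rebound window + pairwise group comparisons.

    ``group_bouts`` maps group name -> one bout list per fly; ``window`` is
    typically the first 3 h of the day following stimulation.  Flies flagged
    dead (``alive`` False) are excluded before testing.  Returns the per-fly
    minutes table and the pairwise Wilcoxon table.
    """
    if len(group_bouts) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    per_group: dict[str, np.ndarray] = {}
    for name, flies in group_bouts.items():
        keep = np.ones(len(flies), dtype=bool) if alive is None else np.asarray(alive[name], dtype=bool)
        minutes = []
        for i, bouts in enumerate(flies):
            if not keep[i]:
                continue
            m = sleep_seconds_in_window(bouts, window) / 60.0
            minutes.append(m)
            rows.append({"group": name, "fly": i, "sleep_min": m})
        if len(minutes) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 live flies")
        per_group[name] = np.asarray(minutes)
    return pd.DataFrame(rows), pairwise_wilcoxon(per_group)


def count_stimuli(
    events: pd.DataFrame, window: tuple[float, float], rois: list[int] | None = None
) -> tuple[pd.Series, float, float]:
    """Per-fly stimulus counts in a window, plus group mean and sample SD."""
    if rois is None:
        rois = sorted(events["roi"].unique()) if len(events) else []
    t0, t1 = window
    counts = {}
    for roi in rois:
        sel = events[(events["roi"] == roi) & (events["t"] >= t0) & (events["t"] < t1)] if len(events) else events
        counts[roi] = int(len(sel))
    s = pd.Series(counts, dtype=int)
    if len(s) == 0:
        return s, 0.0, 0.0
    sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
    return s, float(s.mean()), sd


def tukey_whiskers(values: np.ndarray) -> tuple[float, float]:
    """Boxplot whisker endpoints: last data points within +/-1.5 IQR of hinges."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo_candidates = v[v >= q1 - 1.5 * iqr]
    hi_candidates = v[v <= q3 + 1.5 * iqr]
    return float(lo_candidates.min()), float(hi_candidates.max())
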