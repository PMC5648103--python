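"""Sleep-profile ribbons and Tukey boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sleep import bootstrap_ci, tukey_whiskers

__all__ = ["plot_sleep_profiles", "plot_rebound_boxplot"]


def plot_sleep_profiles(
    profiles: dict[str, np.ndarray],
    bin_s: float,
    out: str | Path,
    n_boot: int = 5000,
    seed: int = 0,
) -> Path:
    """Mean fraction-asleep per bin with a bootstrap 95% CI ribbon per group.

    ``profiles`` maps group name to an (n_flies, n_bins) array.
    """
    fig, ax = plt.subplots(figsize=(8, 3))
    for name, mat in profiles.items():
        mean, lo, hi = bootstrap_ci(np.asarray(mat), n_boot=n_boot, seed=seed)
        hours = (np.arange(mat.shape[1]) + 0.5) * bin_s / 3600.0
        ax.plot(hours, mean, label=name)
        ax.fill_between(hours, lo, hi, alpha=0.3)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("fraction asleep")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def plot_rebound_boxplot(groups: dict[str, np.ndarray], out: str | Path) -> Path:
    """Tukey boxplots (whiskers at the last values within 1.5 IQR) per group."""
    fig, ax = plt.subplots(figsize=(4, 3))
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    ax.boxplot(data, tick_labels=names, whis=1.5)
    for i, v in enumerate(data, start=1):
        lo, hi = tukey_whiskers(v)
        ax.plot([i, i], [lo, hi], alpha=0.0)  # whiskers already drawn; keep scale
    ax.set_ylabel("sleep (min)")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)
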