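"""Cohort bar plot: per-region mean CF with per-cell points."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import CohortResult


def plot_cohort(cohort: CohortResult, path: str | Path | None = None):
    """Bar chart of mean CF per region, SEM error bars, cells as points.

    A dashed line at CF = 1 marks the random-placement control level.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    labels = list(cohort.summaries["region"])
    means = cohort.summaries["mean_cf"].to_numpy()
    sems = cohort.summaries["sem_cf"].to_numpy()

    fig, ax = plt.subplots(figsize=(1.6 * len(labels) + 1.5, 4))
    x = np.arange(len(labels))
    ax.bar(x, means, yerr=sems, capsize=4, color="#9ecae1", edgecolor="k")
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, label in enumerate(labels):
        values = cohort.cf_table[label].dropna().to_numpy()
        ax.plot(i + rng.uniform(-0.12, 0.12, len(values)), values, "ko", ms=4, alpha=0.7)
    ax.axhline(1.0, ls="--", color="gray", lw=1, label="CF = 1 (control)")
    ax.set_xticks(x, labels, rotation=30, ha="right")
    ax.set_ylabel("Colocalization Factor")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
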