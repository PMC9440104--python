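"""Optional matplotlib figures mirroring the standard result layouts.

matplotlib is an optional dependency (install the ``plot`` extra); it is
imported lazily so the rest of the package works without it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_choice_proportions(proportions: pd.DataFrame, by: str, path: str | Path) -> Path:
    """Proportion of effortful choices (95% CI) by condition level and target."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = {"effort": "effort_rank", "reward": "reward"}[by]
    fig, ax = plt.subplots(figsize=(5, 4))
    for target, grp in proportions.groupby("target"):
        grp = grp.sort_values(col)
        yerr = [grp["proportion"] - grp["ci_low"], grp["ci_high"] - grp["proportion"]]
        ax.errorbar(grp[col], grp["proportion"], yerr=yerr, marker="o", capsize=3, label=target)
    ax.set_xlabel(f"{by} level")
    ax.set_ylabel("P(effortful choice)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_overlap(
    deltas: pd.Series, accuracies_pct: pd.Series, path: str | Path, label: str = "other"
) -> Path:
    """Prosocial delta vs. decoding accuracy with the 50% chance line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(accuracies_pct, deltas, alpha=0.7, label=label)
    ax.axvline(50.0, linestyle="--", color="grey")
    ax.axhline(0.0, linestyle="--", color="grey")
    ax.set_xlabel("decoding accuracy (%)")
    ax.set_ylabel("effortful-choice delta (other - self)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
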