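"""Plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .calibration import SEVERITY_LABELS

__all__ = ["plot_cost_shares"]


def plot_cost_shares(shares: pd.DataFrame, path: str | Path) -> None:
    """Stacked-bar chart of cost-component shares per severity stratum."""
    sub = shares[shares["severity"] != "all"].copy()
    pivot = sub.pivot(index="severity", columns="component", values="share_pct")
    pivot.index = [SEVERITY_LABELS[int(s) - 1] for s in pivot.index]
    ax = pivot.plot(kind="bar", stacked=True, figsize=(9, 5), colormap="tab20")
    ax.set_ylabel("% of stratum total direct cost")
    ax.set_xlabel("")
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=7)
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()
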