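"""Timeline plots of component scores with MDC bounds and pain overlay."""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd


def plot_flag_timeline(flags: pd.DataFrame, athlete_id: str, metric: str,
                       path, pain: Optional[pd.DataFrame] = None):
    """Plot one athlete's weekly series for one metric with their MDC bounds,
    colouring weeks by traffic-light status; optionally overlay self-reported
    pain on a secondary axis.  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = flags[(flags["athlete_id"] == athlete_id)
                & (flags["metric"] == metric)].sort_values("week")
    if sel.empty:
        raise ValueError(f"no flags for athlete {athlete_id!r}, metric {metric!r}")
    mean = sel["baseline_mean"].iloc[0]
    mdc95 = sel["mdc95"].iloc[0]

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.axhline(mean, color="grey", lw=0.8, ls=":")
    ax.axhspan(mean - mdc95, mean + mdc95, color="tab:green", alpha=0.12,
               label="baseline mean ± MDC95")
    ax.plot(sel["week"], sel["value"], "-", color="tab:blue", lw=1.0)
    palette = {"green": "tab:green", "yellow": "gold", "red": "tab:red"}
    for status, group in sel.groupby("status"):
        ax.plot(group["week"], group["value"], "o", ms=6,
                color=palette[status], label=status)
    ax.set_xlabel("week")
    ax.set_ylabel(metric)
    ax.set_title(f"{athlete_id}: {metric} vs preseason baseline")

    if pain is not None:
        psel = pain[pain["athlete_id"] == athlete_id].sort_values("week")
        if not psel.empty:
            ax2 = ax.twinx()
            ax2.plot(psel["week"], psel["pain"], "k--", lw=0.9, alpha=0.7,
                     label="pain")
            ax2.set_ylabel("pain (0-10)")
            ax2.set_ylim(0, 10)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
        fig.savefig(path, dpi=120)
    return fig
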