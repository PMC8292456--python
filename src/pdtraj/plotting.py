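"""Optional figure export: trajectory panels (level and z-score vs duration).

Matplotlib is imported lazily so the core pipeline has no hard plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

STRATUM_COLORS = {
    "pd_all": "black",
    "control": "0.6",
    "pdcu": "tab:blue",
    "pdci": "tab:red",
    "abeta_high": "tab:blue",
    "abeta_low": "tab:red",
}


def plot_trajectories(trajectory_table: pd.DataFrame, out_path,
                      value: str = "level", strata=None, markers=None):
    """Panel grid of estimated trajectories, one panel per marker.

    ``trajectory_table`` is the pipeline's ``trajectories.tsv`` layout
    (columns marker, stratum, duration_years, level, z). ``value`` selects
    the level or z-score panel. Writes PNG/SVG/PDF depending on the
    ``out_path`` suffix and returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = trajectory_table
    if strata is not None:
        df = df[df["stratum"].isin(strata)]
    marker_names = markers or sorted(df["marker"].unique())
    n = len(marker_names)
    ncols = min(n, 3)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False)
    for ax, marker in zip(axes.ravel(), marker_names):
        sub = df[df["marker"] == marker]
        for stratum, curve in sub.groupby("stratum"):
            curve = curve.sort_values("duration_years")
            ax.plot(curve["duration_years"], curve[value],
                    color=STRATUM_COLORS.get(stratum), label=stratum)
        ax.axvline(0.0, color="0.85", lw=0.8, zorder=0)
        ax.set_title(marker)
        ax.set_xlabel("years from motor onset")
        ax.set_ylabel("z-score" if value == "z" else "level")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    handles, labels = axes.ravel()[0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="lower right", frameon=False)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return fig
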