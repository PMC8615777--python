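"""Time-series panels of the morphological parameters.

Solid markers denote fully evolved pellets, hollow markers hyphae/clumps —
the plotting convention used for mono-/coculture morphology time courses.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .fractionation import PELLET

_PARAM_COLUMNS = {"A": ("mean_A", "ci_A", "projected area A (µm²)"),
                  "E": ("mean_E", "ci_E", "elongation E (–)"),
                  "Mo": ("mean_Mo", "ci_Mo", "morphology number Mo (–)")}

_CULTURE_COLORS = {"monoA": "k", "monoB": "r", "coculture": "b"}


def plot_timecourse(summaries: pd.DataFrame, parameter: str = "A", ax=None):
    """Plot one parameter's stratum means ± t-confidence bands over time."""
    col, ci_col, label = _PARAM_COLUMNS[parameter]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for (culture, species, fraction), g in summaries.groupby(["culture", "species", "fraction"]):
        g = g.sort_values("time_h")
        color = _CULTURE_COLORS.get(culture, "g")
        solid = fraction == PELLET
        ax.errorbar(
            g["time_h"],
            g[col],
            yerr=g[ci_col],
            marker="o",
            mfc=color if solid else "none",
            color=color,
            linestyle="-" if solid else "--",
            capsize=2,
            label=f"{culture} {species} {'pellets' if solid else 'hyphae/clumps'}",
        )
    if parameter == "A":
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(label)
    ax.legend(fontsize=7)
    return ax
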