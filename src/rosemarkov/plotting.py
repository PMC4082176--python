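"""Quick diagnostic plots for trajectories and cohort runs."""

from __future__ import annotations

import pandas as pd


def plot_ill_share(trajectory: pd.DataFrame, ax=None, equilibrium_share: float | None = None):
    """Plot the mentally ill share of the population over time.

    Accepts a trajectory table with columns year, w, x, y, z (deterministic
    iteration) and optionally draws the closed-form equilibrium share as a
    horizontal reference line.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    total = trajectory[["w", "x", "y", "z"]].sum(axis=1)
    ax.plot(trajectory["year"], 100.0 * trajectory["x"] / total, lw=2, label="ill share")
    if equilibrium_share is not None:
        ax.axhline(100.0 * equilibrium_share, ls="--", color="grey",
                   label="equilibrium")
    ax.set_xlabel("year")
    ax.set_ylabel("mentally ill (% of population)")
    ax.legend()
    return ax
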