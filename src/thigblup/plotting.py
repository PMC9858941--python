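"""Optional thin plotting layer (requires matplotlib, extra ``plots``)."""

from __future__ import annotations

import pandas as pd


def plot_manhattan(table: pd.DataFrame, ax=None):
    """Manhattan plot from :func:`env_compare.manhattan_table` output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    for env, part in table.groupby("env"):
        ax.scatter(part["cumulative_position"], part["pct_var"], s=4, label=env)
    ax.set_xlabel("cumulative genome position (bp)")
    ax.set_ylabel("% explained additive variance")
    ax.legend()
    return ax


def plot_quadrants(table: pd.DataFrame, t_env1: float, t_env2: float, ax=None):
    """Dispersion plot from :func:`env_compare.quadrant_table` output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for quad, part in table.groupby("quadrant"):
        ax.scatter(part["pct_env1"], part["pct_env2"], s=6, label=quad)
    ax.axvline(t_env1, ls="--", lw=0.8, color="grey")
    ax.axhline(t_env2, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("% variance, environment 1")
    ax.set_ylabel("% variance, environment 2")
    ax.legend(fontsize=7)
    return ax
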