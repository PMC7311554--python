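"""Plot helpers for simulated cohorts and power grids."""

from __future__ import annotations

import pandas as pd


def plot_power_curves(power: pd.DataFrame, ax=None):
    """Power vs sample size, one line per effect (seeds averaged)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mean = power.groupby(["effect", "n"])["power"].mean().reset_index()
    for effect, grp in mean.groupby("effect"):
        ax.plot(grp["n"], grp["power"], marker="o", label=effect)
    ax.axhline(0.8, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("participants")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_effort_by_svo(metrics: pd.DataFrame, outcome: str = "response_time_ms", ax=None):
    """Participant-mean effort by SVO angle, split by group context."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    per = (
        metrics.groupby(["participant", "context"])
        .agg(svo=("svo_angle", "first"), y=(outcome, "mean"))
        .reset_index()
    )
    for ctx, grp in per.groupby("context"):
        ax.scatter(grp["svo"], grp["y"], s=12, alpha=0.6, label=ctx)
    ax.set_xlabel("SVO angle (deg)")
    ax.set_ylabel(outcome)
    ax.legend()
    return ax
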