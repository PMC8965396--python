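"""Figure replicas: paired rate comparison and the STS x ICC quadrant scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_rate_comparison(summaries: pd.DataFrame):
    """Paired dot plot of per-species STS and ICC for the two rates.

    ``summaries`` is a decomposition summary table (species, rate, statistic,
    mean, sd).  Point area scales with the posterior sd; dashed lines join a
    species' productivity and survival estimates.
    """
    stats = ["STS", "ICC"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, stat in zip(axes, stats):
        sub = summaries[summaries["statistic"] == stat]
        wide_mean = sub.pivot(index="species_code", columns="rate", values="mean")
        wide_sd = sub.pivot(index="species_code", columns="rate", values="sd")
        x = {"productivity": 0.0, "survival": 1.0}
        for sp in wide_mean.index:
            ax.plot(
                [x[r] for r in wide_mean.columns],
                wide_mean.loc[sp],
                "--",
                color="0.7",
                lw=0.8,
                zorder=1,
            )
        for rate in wide_mean.columns:
            ax.scatter(
                [x[rate]] * len(wide_mean),
                wide_mean[rate],
                s=20 + 400 * wide_sd[rate],
                alpha=0.6,
                zorder=2,
                label=rate,
            )
        ax.axhline(0.5, color="k", lw=0.5)
        ax.set_xticks(list(x.values()), list(x.keys()))
        ax.set_xlim(-0.5, 1.5)
        ax.set_ylim(0, 1)
        ax.set_title(stat)
    axes[0].set_ylabel("posterior mean")
    fig.tight_layout()
    return fig


def plot_quadrants(quadrants: pd.DataFrame):
    """STS x ICC scatter per rate with quadrant lines at 0.5."""
    rates = sorted(quadrants["rate"].unique())
    fig, axes = plt.subplots(1, len(rates), figsize=(4.5 * len(rates), 4), squeeze=False)
    for ax, rate in zip(axes[0], rates):
        sub = quadrants[quadrants["rate"] == rate]
        ax.scatter(sub["sts_mean"], sub["icc_mean"], s=25)
        for _, row in sub.iterrows():
            ax.annotate(
                row["species_code"], (row["sts_mean"], row["icc_mean"]),
                fontsize=6, xytext=(2, 2), textcoords="offset points",
            )
        ax.axvline(0.5, color="k", lw=0.8)
        ax.axhline(0.5, color="k", lw=0.8)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel("STS (spatial fraction)")
        ax.set_title(rate)
        for label, xy in {"i": (0.75, 0.04), "ii": (0.75, 0.94), "iii": (0.25, 0.04), "iv": (0.25, 0.94)}.items():
            ax.text(*xy, label, transform=ax.transAxes, ha="center", color="0.4")
    axes[0][0].set_ylabel("ICC (synchrony)")
    fig.tight_layout()
    return fig
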