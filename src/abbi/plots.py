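"""Figure helpers for the quarterly index and associated-ratio series."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def _quarter_axis(df: pd.DataFrame) -> pd.Series:
    return df["year"] + (df["quarter"] - 1) / 4.0


def plot_index_series(series: pd.DataFrame, path, value: str = "n_total",
                      se_col: str = "se") -> None:
    """One panel per species: index per quarter, one line per phi, ±s.e. band."""
    species = sorted(series["species"].unique())
    fig, axes = plt.subplots(len(species), 1, figsize=(8, 2.8 * len(species)),
                             sharex=True, squeeze=False)
    for ax, sp in zip(axes.ravel(), species):
        sub = series[series["species"] == sp]
        for phi, grp in sub.groupby("phi"):
            grp = grp.sort_values(["year", "quarter"])
            x = _quarter_axis(grp)
            ax.plot(x, grp[value], marker="o", ms=3, label=f"phi={phi:g}")
            if se_col in grp and grp[se_col].notna().any():
                ax.fill_between(x, grp[value] - grp[se_col],
                                grp[value] + grp[se_col], alpha=0.2)
        ax.set_title(sp)
        ax.set_ylabel(value)
        ax.legend(fontsize=8)
    axes.ravel()[-1].set_xlabel("year")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_associated_ratio(ratio: pd.DataFrame, path) -> None:
    """Associated/total biomass ratio per quarter, one line per phi."""
    species = sorted(ratio["species"].unique())
    fig, axes = plt.subplots(len(species), 1, figsize=(8, 2.8 * len(species)),
                             sharex=True, squeeze=False)
    for ax, sp in zip(axes.ravel(), species):
        sub = ratio[ratio["species"] == sp]
        for phi, grp in sub.groupby("phi"):
            grp = grp.sort_values(["year", "quarter"])
            ax.plot(_quarter_axis(grp), grp["ratio"], marker="o", ms=3,
                    label=f"phi={phi:g}")
        ax.set_ylim(0, 1)
        ax.set_title(sp)
        ax.set_ylabel("associated / total")
        ax.legend(fontsize=8)
    axes.ravel()[-1].set_xlabel("year")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
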