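"""Summary figures for the benchmark experiments.

All functions write a file and return its path; they accept the tidy
tables produced by :mod:`gelimpute.benchmark`.  The Venn renderer is a
small circles-and-counts drawing for 2 or 3 sets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def rmse_boxplot(table: pd.DataFrame, path: str | Path, fraction: float | None = None) -> Path:
    """Per-method NRMSE distributions at one missing fraction."""
    df = table
    if fraction is not None:
        df = df[df["fraction"] == fraction]
    methods = list(dict.fromkeys(df["method"]))
    data = [df.loc[df["method"] == m, "nrmse"].dropna() for m in methods]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(methods)), 4))
    ax.boxplot(data, tick_labels=methods)
    ax.set_ylabel("normalized RMSE")
    ax.set_xlabel("imputation method")
    if fraction is not None:
        ax.set_title(f"{fraction:.0%} of cells removed")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def rmse_vs_fraction(table: pd.DataFrame, path: str | Path) -> Path:
    """Mean NRMSE as a function of the missing fraction, one line per method."""
    fig, ax = plt.subplots(figsize=(6, 4))
    grp = table.groupby(["method", "fraction"])["nrmse"].mean().reset_index()
    for m in dict.fromkeys(table["method"]):
        sub = grp[grp["method"] == m]
        ax.plot(sub["fraction"], sub["nrmse"], marker="o", label=m)
    ax.set_xlabel("fraction of cells removed")
    ax.set_ylabel("mean normalized RMSE")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def variance_bars(table: pd.DataFrame, path: str | Path, fraction: float | None = None) -> Path:
    """Mean average variance per method, with the complete-data reference line."""
    df = table
    if fraction is not None:
        df = df[df["fraction"] == fraction]
    grp = df.groupby("method", sort=False)["avg_variance"].mean()
    complete = float(df["complete_avg_variance"].iloc[0])
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(grp)), 4))
    ax.bar(grp.index, grp.values)
    ax.axhline(complete, linestyle="-.", color="k", label="complete data")
    ax.set_ylabel("mean average spot variance")
    ax.legend()
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def median_discovery_bars(medians: pd.DataFrame, path: str | Path) -> Path:
    """Grouped bars of median discoveries per test × method."""
    pivot = medians.pivot(index="test", columns="method", values="median_discoveries")
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(pivot)), 4))
    pivot.plot.bar(ax=ax)
    ax.set_ylabel("median discoveries")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def venn_diagram(sets: Mapping[str, set], path: str | Path, title: str = "") -> Path:
    """Circles-and-counts Venn drawing for 2 or 3 labelled sets."""
    from .benchmark import overlap_summary

    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValueError("venn_diagram supports 2 or 3 sets")
    regions = overlap_summary(sets)
    fig, ax = plt.subplots(figsize=(5, 5))
    if len(labels) == 2:
        centers = [(-0.5, 0.0), (0.5, 0.0)]
        text_at = {
            (labels[0],): (-1.0, 0.0),
            (labels[1],): (1.0, 0.0),
            tuple(sorted(labels)): (0.0, 0.0),
        }
    else:
        centers = [(-0.5, -0.3), (0.5, -0.3), (0.0, 0.57)]
        text_at = {
            (labels[0],): (-1.0, -0.5),
            (labels[1],): (1.0, -0.5),
            (labels[2],): (0.0, 1.1),
            tuple(sorted((labels[0], labels[1]))): (0.0, -0.55),
            tuple(sorted((labels[0], labels[2]))): (-0.55, 0.35),
            tuple(sorted((labels[1], labels[2]))): (0.55, 0.35),
            tuple(sorted(labels)): (0.0, 0.0),
        }
    for (x, y), lab in zip(centers, labels):
        ax.add_patch(plt.Circle((x, y), 1.0, fill=False, linewidth=1.5))
        ax.annotate(lab, (x, y + 1.05), ha="center", fontsize=9)
    for key, (x, y) in text_at.items():
        ax.text(x, y, str(regions.get(key, 0)), ha="center", va="center")
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
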