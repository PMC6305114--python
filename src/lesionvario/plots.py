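"""Plotting helpers: every figure is a derived view of a table, never the
source of any reported number."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ldp import EvolutionPath
from .stats import box_summary, marginal_density

SUBGROUP_COLORS = {"F1": "#f4a6c0", "F2": "#d7191c", "M1": "#9ecae1", "M2": "#2c7bb6"}


def _color(label: str) -> str:
    return SUBGROUP_COLORS.get(label, "0.4")


def ldp_scatter(descriptors: pd.DataFrame, hue: str | None = None, path: str | Path | None = None):
    """LDP point cloud: one square per pattern, A on x, C on y."""
    fig, ax = plt.subplots(figsize=(6, 5))
    if hue and hue in descriptors:
        for value, sub in descriptors.groupby(hue):
            ax.scatter(sub["A"], sub["C"], marker="s", s=18, label=str(value),
                       color=_color(str(value)))
        ax.legend(title=hue)
    else:
        ax.scatter(descriptors["A"], descriptors["C"], marker="s", s=18, color="0.3")
    ax.set_xlabel("A  (mean ln range)")
    ax.set_ylabel("C  (mean ln sill)")
    ax.set_title("Lesion discrimination plot")
    return _finish(fig, path)


def evolution_plot(
    paths: Mapping[str, EvolutionPath],
    labels: Mapping[str, str],
    total_vectors: pd.DataFrame | None = None,
    path: str | Path | None = None,
):
    """Per-subject evolution vectors (thin) and subgroup total vectors (bold)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for sid, p in paths.items():
        color = _color(labels.get(sid, ""))
        ax.annotate(
            "",
            xy=(p.last.A, p.last.C),
            xytext=(p.first.A, p.first.C),
            arrowprops=dict(arrowstyle="->", color=color, lw=0.8, alpha=0.6),
        )
    if total_vectors is not None:
        for row in total_vectors.itertuples(index=False):
            ax.annotate(
                "",
                xy=(row.A_end, row.C_end),
                xytext=(row.A_start, row.C_start),
                arrowprops=dict(arrowstyle="->", color=_color(row.subgroup), lw=2.5),
            )
    ax.set_xlabel("A  (mean ln range)")
    ax.set_ylabel("C  (mean ln sill)")
    ax.set_title("Lesion-pattern evolution (first -> last MRI)")
    return _finish(fig, path)


def box_whisker_longitudinal(
    descriptors: pd.DataFrame,
    assignments: pd.DataFrame,
    response: str = "A",
    path: str | Path | None = None,
):
    """Box-whisker evolution per subgroup and timepoint (5/95% whiskers)."""
    merged = descriptors.merge(assignments[["subject_id", "label"]], on="subject_id")
    groups = sorted(merged["label"].unique())
    tps = sorted(merged["timepoint"].unique())
    fig, ax = plt.subplots(figsize=(1.4 * len(groups) * len(tps) / 2 + 2, 4))
    pos = 0
    ticks, ticklabels = [], []
    for g in groups:
        for t in tps:
            vals = merged.loc[
                (merged["label"] == g) & (merged["timepoint"] == t), response
            ].to_numpy()
            if vals.size == 0:
                continue
            s = box_summary(vals)
            ax.bxp(
                [
                    {
                        "med": s.median,
                        "q1": s.q25,
                        "q3": s.q75,
                        "whislo": s.whisker_low,
                        "whishi": s.whisker_high,
                        "fliers": s.outliers,
                    }
                ],
                positions=[pos],
                widths=0.7,
                showfliers=True,
                boxprops=dict(color=_color(g)),
                medianprops=dict(color="black"),
            )
            ticks.append(pos)
            ticklabels.append(f"{g}\nt{t}")
            pos += 1
        pos += 0.8
    ax.set_xticks(ticks)
    ax.set_xticklabels(ticklabels, fontsize=7)
    ax.set_ylabel(response)
    ax.set_title(f"Longitudinal {response} distributions (whiskers: 5/95%)")
    return _finish(fig, path)


def density_panel(values_by_group: Mapping[str, Sequence[float]], path: str | Path | None = None):
    """Marginal density plots, one curve per group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, values in values_by_group.items():
        grid, dens = marginal_density(values)
        ax.plot(grid, dens, label=name, color=_color(name) if name in SUBGROUP_COLORS else None)
    ax.set_ylabel("density")
    ax.legend()
    return _finish(fig, path)


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(str(path), dpi=150)
        plt.close(fig)
        return None
    return fig
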