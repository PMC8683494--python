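"""Publication-style plots for coverage curves and region panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_CLASS_COLORS = {"S": "#1f77b4", "S+G": "#ff7f0e", "S+G+D": "#2ca02c", "D": "#d62728"}


def plot_coverage_curves(
    curve_summary: pd.DataFrame,
    path: str | Path,
    tissue: str = "gm",
    scope: str = "per_contact",
) -> None:
    """Median (IQR-shaded) coverage vs RoI radius, one line per implant class."""
    sel = curve_summary[
        (curve_summary.tissue == tissue) & (curve_summary.scope == scope)
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    for cls, sub in sel.groupby("implant_class"):
        sub = sub.sort_values("radius_mm")
        color = _CLASS_COLORS.get(cls)
        ax.plot(sub.radius_mm, sub["median"], label=cls, color=color)
        ax.fill_between(sub.radius_mm, sub.q1, sub.q3, alpha=0.2, color=color)
    ax.set_xlabel("radius of influence (mm)")
    unit = "mm$^3$/contact" if scope == "per_contact" else "mm$^3$"
    tissue_name = {"gm": "gray matter", "wm": "white matter"}.get(tissue, tissue)
    ax.set_ylabel(f"{tissue_name} coverage ({unit})")
    ax.legend(title="implant class")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_region_coverage(region_summary: pd.DataFrame, path: str | Path) -> None:
    """Bar panel of median region coverage per class, with inclusion counts."""
    regions = sorted(region_summary.region.unique())
    fig, axes = plt.subplots(
        1, len(regions), figsize=(2.2 * len(regions), 3.2), sharey=False
    )
    if len(regions) == 1:
        axes = [axes]
    for ax, region in zip(axes, regions):
        sub = region_summary[region_summary.region == region]
        classes = sub.implant_class.tolist()
        med = sub["median"].fillna(0.0)
        ax.bar(classes, med, color=[_CLASS_COLORS.get(c) for c in classes])
        labels = [f"{c}\n({int(n)})" for c, n in zip(classes, sub.n_included)]
        ax.set_xticks(range(len(classes)), labels, fontsize=7)
        ax.set_title(region, fontsize=9)
    axes[0].set_ylabel("GM coverage (mm$^3$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
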