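"""Report figures: payment-category shares, benefit groups, monthly gain."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .panel import PanelDataset
from .summarize import benefit_proportions, category_percentages

_CATEGORY_COLORS = {"bonus": "#2a9d8f", "base": "#e9c46a", "penalty": "#e76f51"}


def save_report_plots(scored: PanelDataset, out_dir: Path) -> dict[str, Path]:
    """Write the three standard report figures as PNG; returns paths."""
    out: dict[str, Path] = {}

    cats = category_percentages(scored)
    regions = sorted(cats["region"].unique())
    fig, axes = plt.subplots(1, len(regions), figsize=(4 * len(regions), 3.2),
                             sharey=True, squeeze=False)
    for ax, region in zip(axes[0], regions):
        sub = cats[cats["region"] == region]
        bottom = {c: 0.0 for c in sub["component"].unique()}
        for cat in ("bonus", "base", "penalty"):
            rows = sub[sub["category"] == cat]
            ax.bar(rows["component"], rows["percentage"],
                   bottom=[bottom[c] for c in rows["component"]],
                   label=cat, color=_CATEGORY_COLORS[cat])
            for comp, pct in zip(rows["component"], rows["percentage"]):
                bottom[comp] += pct
        ax.set_title(region)
        ax.set_ylabel("% of records")
    axes[0][-1].legend(fontsize=8)
    fig.suptitle("Payment categories by milk component")
    fig.tight_layout()
    path = out_dir / "fig_category_percentages.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    out["fig_category_percentages"] = path

    by_region = benefit_proportions(scored, {"region"})
    fig, ax = plt.subplots(figsize=(5, 3.2))
    width = 0.25
    for i, grp in enumerate(("n_gain", "n_none", "n_loss")):
        pct = 100.0 * by_region[grp] / by_region["n_records"]
        ax.bar([x + (i - 1) * width for x in range(len(by_region))], pct,
               width=width, label=grp.removeprefix("n_"))
    ax.set_xticks(range(len(by_region)), by_region["region"])
    ax.set_ylabel("% of records")
    ax.set_title("Benefit groups by region")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / "fig_benefit_groups.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    out["fig_benefit_groups"] = path

    monthly = benefit_proportions(scored, {"region", "month"})
    fig, ax = plt.subplots(figsize=(6, 3.2))
    for region, sub in monthly.groupby("region"):
        ax.plot(sub["month"], sub["pct_gain"], marker="o", ms=3, label=region)
    ax.set_xlabel("panel month")
    ax.set_ylabel("% in benefit-gain group")
    ax.set_title("Monthly benefit-gain percentage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / "fig_monthly_gain.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    out["fig_monthly_gain"] = path
    return out
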