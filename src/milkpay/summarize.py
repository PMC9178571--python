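"""Descriptive summaries of scored BTM panels.

Three views of a scored panel: the share of records in each payment
category (bonus / base / penalty) per milk component, the benefit-group
proportions (gain / loss / none) overall or by region and month, and the
most frequent payment-category patterns — ordered (fat, snf, scc)
category triples — per region.
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd

from .panel import PanelDataset
from .schedule import Category, Component

logger = logging.getLogger(__name__)

_CATEGORY_RANK = {
    Category.BONUS.value: 0,
    Category.BASE.value: 1,
    Category.PENALTY.value: 2,
}
_COMPONENTS = [c.value for c in Component]
_CATEGORIES = [c.value for c in Category]


def category_percentages(
    data: PanelDataset, by_region: bool = True, by_label: bool = False
) -> pd.DataFrame:
    """Percentage of records per payment category (or class label).

    Returns a tidy frame (region, component, category, n, percentage);
    within each (region, component) the percentages sum to 100.  With
    ``by_label`` the finer class labels (A++ … E) are tallied instead of
    the three coarse categories.
    """
    data.require_scored()
    df = data.df
    if df.empty:
        raise ValueError("cannot summarize an empty panel")
    region_col = df["region"] if by_region else pd.Series("all", index=df.index)
    suffix = "_class" if by_label else "_category"
    parts = []
    for comp in _COMPONENTS:
        counts = (
            pd.DataFrame({"region": region_col, "category": df[comp + suffix]})
            .groupby(["region", "category"], sort=True)
            .size()
            .rename("n")
            .reset_index()
        )
        counts["component"] = comp
        parts.append(counts)
    out = pd.concat(parts, ignore_index=True)
    if not by_label:
        # include zero-count categories so every (region, component) has 3 rows
        regions = sorted(region_col.unique())
        full = pd.DataFrame(
            product(regions, _COMPONENTS, _CATEGORIES),
            columns=["region", "component", "category"],
        )
        out = full.merge(out, how="left", on=["region", "component", "category"])
        out["n"] = out["n"].fillna(0).astype(int)
    totals = out.groupby(["region", "component"])["n"].transform("sum")
    out["percentage"] = 100.0 * out["n"] / totals
    if not by_label:
        out["category"] = pd.Categorical(
            out["category"], categories=_CATEGORIES, ordered=True
        )
        out = out.sort_values(["region", "component", "category"])
    return out[["region", "component", "category", "n", "percentage"]].reset_index(
        drop=True
    )


def benefit_proportions(
    data: PanelDataset, group_by: set[str] | frozenset[str] = frozenset({"region"})
) -> pd.DataFrame:
    """Benefit-group counts and gain percentage per group.

    ``group_by`` is ``{"region"}`` or ``{"region", "month"}``; with month
    the chronological index t = 1..T is used.  Region-month cells with no
    records are omitted with a logged warning.
    """
    data.require_scored()
    df = data.df
    if df.empty:
        raise ValueError("cannot summarize an empty panel")
    group_by = set(group_by)
    if not group_by <= {"region", "month"} or "region" not in group_by:
        raise ValueError(f"unsupported group_by: {group_by}")
    keys = ["region"]
    work = df[["region", "benefit_group"]].copy()
    if "month" in group_by:
        work["month"] = data.month_index().to_numpy()
        keys.append("month")
    counts = (
        work.groupby(keys, sort=True)["benefit_group"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["gain", "loss", "none"], fill_value=0)
        .reset_index()
    )
    if "month" in group_by:
        expected = set(product(work["region"].unique(), range(1, data.n_months + 1)))
        observed = set(zip(counts["region"], counts["month"]))
        for region, t in sorted(expected - observed):
            logger.warning("no records for region=%s month=%s; cell omitted", region, t)
    counts = counts.rename(
        columns={"gain": "n_gain", "loss": "n_loss", "none": "n_none"}
    )
    counts["n_records"] = counts[["n_gain", "n_loss", "n_none"]].sum(axis=1)
    counts["pct_gain"] = 100.0 * counts["n_gain"] / counts["n_records"]
    cols = keys + ["n_records", "n_gain", "n_loss", "n_none", "pct_gain"]
    return counts[cols]


def top_patterns(data: PanelDataset, region: str, k: int = 5) -> pd.DataFrame:
    """The ``k`` most frequent (fat, snf, scc) payment-category patterns.

    Returns columns fat, snf, scc, count, percentage; percentages are of
    all the region's records.  Ties in count are broken by category rank
    (bonus before base before penalty), component-wise in (fat, snf, scc)
    order, so the output is deterministic.
    """
    data.require_scored()
    if k < 1:
        raise ValueError("k must be >= 1")
    df = data.df[data.df["region"] == region]
    if df.empty:
        raise ValueError(f"no records for region {region!r}")
    counts = (
        df.groupby(["fat_category", "snf_category", "scc_category"], sort=False)
        .size()
        .rename("count")
        .reset_index()
        .rename(
            columns={"fat_category": "fat", "snf_category": "snf", "scc_category": "scc"}
        )
    )
    for col in ("fat", "snf", "scc"):
        counts[f"_{col}_rank"] = counts[col].map(_CATEGORY_RANK)
    counts = counts.sort_values(
        ["count", "_fat_rank", "_snf_rank", "_scc_rank"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).drop(columns=["_fat_rank", "_snf_rank", "_scc_rank"])
    counts["percentage"] = 100.0 * counts["count"] / len(df)
    if k > len(counts):
        logger.info(
            "requested top %d patterns but only %d distinct; returning all",
            k,
            len(counts),
        )
    return counts.head(k).reset_index(drop=True)
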