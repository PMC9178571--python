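"""Panel container for monthly bulk-tank-milk records.

A :class:`PanelDataset` wraps a pandas DataFrame with one row per
farm-month and a documented column set.  Calendar months are mapped to a
chronological index t = 1..T, which is the time variable of both the
descriptive summaries and the mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "farm_id",
    "region",
    "year",
    "month",
    "fat_pct",
    "snf_pct",
    "scc_thousand",
]

SCORED_COLUMNS = [
    "fat_class",
    "snf_class",
    "scc_class",
    "fat_category",
    "snf_category",
    "scc_category",
    "final_price_baht",
    "benefit_group",
]


@dataclass
class PanelDataset:
    """Monthly BTM panel with optional attached payment scores.

    Invariants enforced on construction: required columns present,
    (farm_id, year, month) unique, every farm in exactly one region,
    months in 1..12, fat/snf positive, scc non-negative.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        df = self.df
        dup = df.duplicated(subset=["farm_id", "year", "month"])
        if dup.any():
            rows = df.index[dup][:5].tolist()
            raise ValueError(f"duplicate (farm_id, year, month) rows: {rows}")
        nregions = df.groupby("farm_id", sort=False)["region"].nunique()
        multi = nregions[nregions > 1]
        if len(multi):
            raise ValueError(
                f"farms assigned to multiple regions: {multi.index[:5].tolist()}"
            )
        if not df["month"].between(1, 12).all():
            raise ValueError("month values must be in 1..12")
        if (df["fat_pct"] <= 0).any() or (df["snf_pct"] <= 0).any():
            raise ValueError("fat_pct and snf_pct must be positive")
        if (df["scc_thousand"] < 0).any():
            raise ValueError("scc_thousand must be non-negative")

    # -- derived index sets -------------------------------------------

    @property
    def farms(self) -> list:
        return sorted(self.df["farm_id"].unique().tolist())

    @property
    def regions(self) -> list[str]:
        return sorted(self.df["region"].unique().tolist())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def month_index(self) -> pd.Series:
        """Chronological month index t = 1..T over (year, month) pairs."""
        key = self.df["year"].astype(int) * 12 + self.df["month"].astype(int)
        codes = key.rank(method="dense").astype(int)
        return codes.rename("t")

    @property
    def n_months(self) -> int:
        return int(self.month_index().max())

    @property
    def is_scored(self) -> bool:
        return "benefit_group" in self.df.columns

    def require_scored(self) -> None:
        if not self.is_scored:
            raise ValueError(
                "panel has no payment scores; run score_panel / the score "
                "stage first"
            )

    def with_scores(self, schedule=None) -> "PanelDataset":
        """Return a scored copy of this panel (see ``schedule.score_panel``)."""
        from .schedule import score_panel

        return PanelDataset(score_panel(self.df, schedule))
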