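"""Descriptive summaries versus independent brute-force recounts."""

import numpy as np
import pandas as pd
import pytest

from milkpay.panel import PanelDataset
from milkpay.summarize import benefit_proportions, category_percentages, top_patterns
from tests.conftest import make_panel, random_scored_panel

# ---------------------------------------------------------------------------
# brute-force oracles: plain loops, no grouping machinery
# ---------------------------------------------------------------------------


def brute_category_percentages(df: pd.DataFrame) -> dict:
    out = {}
    for region in set(df["region"]):
        rows = df[df["region"] == region]
        for comp in ("fat", "snf", "scc"):
            for cat in ("bonus", "base", "penalty"):
                n = 0
                for _, row in rows.iterrows():
                    if row[f"{comp}_category"] == cat:
                        n += 1
                out[(region, comp, cat)] = (n, 100.0 * n / len(rows))
    return out


def brute_benefit_counts(df: pd.DataFrame, months: pd.Series | None) -> dict:
    out = {}
    for i, (_, row) in enumerate(df.iterrows()):
        key = (row["region"],) if months is None else (row["region"], months.iloc[i])
        tally = out.setdefault(key, {"gain": 0, "loss": 0, "none": 0})
        tally[row["benefit_group"]] += 1
    return out


def brute_pattern_counts(df: pd.DataFrame, region: str) -> dict:
    out = {}
    for _, row in df.iterrows():
        if row["region"] != region:
            continue
        key = (row["fat_category"], row["snf_category"], row["scc_category"])
        out[key] = out.get(key, 0) + 1
    return out


# ---------------------------------------------------------------------------


def test_category_percentages_match_brute_force(rng):
    for _ in range(30):
        panel = random_scored_panel(rng)
        expected = brute_category_percentages(panel.df)
        table = category_percentages(panel)
        for _, row in table.iterrows():
            n, pct = expected[(row["region"], row["component"], str(row["category"]))]
            assert row["n"] == n
            assert row["percentage"] == pytest.approx(pct)


def test_benefit_proportions_match_brute_force(rng):
    for _ in range(30):
        panel = random_scored_panel(rng)
        months = panel.month_index()
        for group_by, keys in [({"region"}, None), ({"region", "month"}, months)]:
            expected = brute_benefit_counts(panel.df, keys)
            table = benefit_proportions(panel, group_by)
            assert len(table) == len(expected)
            for _, row in table.iterrows():
                key = (
                    (row["region"],)
                    if keys is None
                    else (row["region"], row["month"])
                )
                tally = expected[key]
                assert row["n_gain"] == tally["gain"]
                assert row["n_loss"] == tally["loss"]
                assert row["n_none"] == tally["none"]
                total = sum(tally.values())
                assert row["n_records"] == total
                assert row["pct_gain"] == pytest.approx(100.0 * tally["gain"] / total)


def test_top_patterns_match_brute_force(rng):
    for _ in range(30):
        panel = random_scored_panel(rng)
        for region in panel.regions:
            expected = brute_pattern_counts(panel.df, region)
            table = top_patterns(panel, region, k=27)
            assert len(table) == len(expected)
            assert table["count"].is_monotonic_decreasing
            for _, row in table.iterrows():
                assert expected[(row["fat"], row["snf"], row["scc"])] == row["count"]


def test_summaries_are_permutation_invariant(rng):
    panel = random_scored_panel(rng, n_max=80)
    perm = rng.permutation(len(panel.df))
    shuffled = PanelDataset(panel.df.iloc[perm].reset_index(drop=True))
    a = category_percentages(panel).reset_index(drop=True)
    b = category_percentages(shuffled).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(
        benefit_proportions(panel, {"region", "month"}).reset_index(drop=True),
        benefit_proportions(shuffled, {"region", "month"}).reset_index(drop=True),
    )
    for region in panel.regions:
        pd.testing.assert_frame_equal(
            top_patterns(panel, region, 5), top_patterns(shuffled, region, 5)
        )


def test_category_percentages_hand_count():
    # 10 records: 4 scc-bonus, 2 scc-base, 4 scc-penalty -> 40/20/40
    panel = make_panel(
        fat=3.5,
        snf=8.4,
        scc=[100, 150, 250, 350, 450, 480, 600, 800, 900, 1200],
    ).with_scores()
    table = category_percentages(panel)
    scc = table[table["component"] == "scc"].set_index("category")["percentage"]
    assert scc["bonus"] == pytest.approx(40.0)
    assert scc["base"] == pytest.approx(20.0)
    assert scc["penalty"] == pytest.approx(40.0)
    sums = table.groupby(["region", "component"], observed=True)["percentage"].sum()
    assert np.allclose(sums, 100.0)


def test_benefit_proportions_hand_count():
    # FP +100, -100, 0 -> one record in each benefit group
    panel = make_panel(
        fat=[3.9, 3.5, 3.5], snf=[8.4, 8.3, 8.4], scc=[600, 450, 450]
    ).with_scores()
    table = benefit_proportions(panel, {"region"})
    row = table.iloc[0]
    assert (row["n_gain"], row["n_loss"], row["n_none"]) == (1, 1, 1)


def test_top_patterns_hand_count_and_tie_break():
    # 3x (bonus,bonus,penalty), 2x (bonus,penalty,penalty), 1x (base,base,base)
    panel = make_panel(
        fat=[4.2, 4.2, 4.2, 4.2, 4.2, 3.5],
        snf=[8.6, 8.6, 8.6, 8.2, 8.2, 8.4],
        scc=[600, 600, 600, 600, 600, 450],
    ).with_scores()
    table = top_patterns(panel, "central", k=2)
    assert list(table.iloc[0][["fat", "snf", "scc"]]) == ["bonus", "bonus", "penalty"]
    assert table.iloc[0]["percentage"] == pytest.approx(50.0)
    assert list(table.iloc[1][["fat", "snf", "scc"]]) == ["bonus", "penalty", "penalty"]
    assert table.iloc[1]["percentage"] == pytest.approx(100.0 / 3.0)
    # equal counts order by category rank, bonus before base before penalty
    tie = make_panel(
        fat=[4.2, 3.5], snf=[8.6, 8.4], scc=[100, 450]
    ).with_scores()
    t = top_patterns(tie, "central", k=2)
    assert list(t.iloc[0][["fat", "snf", "scc"]]) == ["bonus", "bonus", "bonus"]


def test_month_index_is_chronological():
    panel = make_panel(
        fat=[3.5] * 4,
        snf=[8.4] * 4,
        scc=[450] * 4,
        year=[2018, 2018, 2019, 2019],
        month=[1, 12, 1, 12],
    )
    assert panel.month_index().tolist() == [1, 2, 3, 4]


def test_unscored_and_empty_inputs_raise():
    panel = make_panel(fat=3.5, snf=8.4, scc=450)
    with pytest.raises(ValueError, match="scores"):
        category_percentages(panel)
    with pytest.raises(ValueError, match="region"):
        top_patterns(panel.with_scores(), "nowhere", 1)
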