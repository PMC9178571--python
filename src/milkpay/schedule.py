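"""Milk-quality payment schedule: band classification, final price, compliance.

The Thai payment program based on milk quality (PPBMQ) prices raw bulk tank
milk (BTM) by three components — fat %, solids-not-fat (SNF) %, and somatic
cell count (SCC) — each mapped to an ordered set of payment bands.  A band
carries a signed price adjustment in baht per 1000 kg of milk: positive
(bonus), zero (base), or negative (penalty).  The final price (FP) of a
farm-month record is the sum of its three component adjustments, and the
sign of FP places the record in the benefit-gain (FP > 0), benefit-loss
(FP < 0), or no-benefit (FP = 0) group.

The schedule itself is data, not code: the packaged default lives in
``data/schedule_th2016.yaml`` and alternative what-if schedules can be
loaded from the same format.

Fat and SNF are compared at 2-decimal resolution (inputs are rounded
half-away-from-zero before lookup); SCC, stored in thousands of cells/mL,
is compared as integer cells/mL.  At these resolutions the packaged bands
partition the admissible range of each component exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Region",
    "Component",
    "Category",
    "BenefitGroup",
    "BTMRecord",
    "PaymentBand",
    "PaymentSchedule",
    "ClassAssignment",
    "PaymentResult",
    "ComplianceResult",
    "default_schedule",
    "classify_component",
    "score_record",
    "score_panel",
    "check_compliance",
    "SCC_LIMIT_THOUSANDS",
    "FAT_MINIMUM_PCT",
    "SNF_MINIMUM_PCT",
]

#: Thai raw-milk standards: SCC may not exceed 500,000 cells/mL and
#: fat / SNF may not fall below 3.35 % / 8.25 %.
SCC_LIMIT_THOUSANDS = 500.0
FAT_MINIMUM_PCT = 3.35
SNF_MINIMUM_PCT = 8.25


class Region(str, enum.Enum):
    NORTH = "north"
    CENTRAL = "central"


class Component(str, enum.Enum):
    FAT = "fat"
    SNF = "snf"
    SCC = "scc"


class Category(str, enum.Enum):
    BONUS = "bonus"
    BASE = "base"
    PENALTY = "penalty"


class BenefitGroup(str, enum.Enum):
    GAIN = "gain"
    LOSS = "loss"
    NONE = "none"


def _round2(value: float) -> float:
    """Round half-away-from-zero to 2 decimals (values here are positive)."""
    return math.floor(value * 100.0 + 0.5 + 1e-9) / 100.0


@dataclass(frozen=True)
class BTMRecord:
    """One monthly bulk-tank-milk observation from a single farm.

    ``scc`` is stored in thousands of cells per mL (320 means 320,000
    cells/mL), following the convention of the national testing program.
    """

    farm_id: str
    region: Region
    year: int
    month: int
    fat: float
    snf: float
    scc: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if self.fat <= 0:
            raise ValueError(f"fat must be positive, got {self.fat}")
        if self.snf <= 0:
            raise ValueError(f"snf must be positive, got {self.snf}")
        if self.scc < 0:
            raise ValueError(f"scc must be non-negative, got {self.scc}")


@dataclass(frozen=True)
class PaymentBand:
    """One interval of a component's payment scale.

    ``lower``/``upper`` are inclusive; ``None`` means unbounded.  The
    category is implied by the sign of the adjustment: bonus (> 0),
    base (= 0), penalty (< 0).  ``usd`` is the fixed printed display
    conversion, never used in computation.
    """

    component: Component
    lower: float | None
    upper: float | None
    label: str
    adjustment: float
    usd: float | None = None

    @property
    def category(self) -> Category:
        if self.adjustment > 0:
            return Category.BONUS
        if self.adjustment < 0:
            return Category.PENALTY
        return Category.BASE

    def contains(self, value: float) -> bool:
        lo = -math.inf if self.lower is None else self.lower
        hi = math.inf if self.upper is None else self.upper
        return lo <= value <= hi


@dataclass(frozen=True)
class ClassAssignment:
    component: Component
    label: str
    category: Category
    adjustment: float


@dataclass(frozen=True)
class PaymentResult:
    """Per-component class assignments, final price, and benefit group."""

    assignments: Mapping[Component, ClassAssignment]
    final_price: float
    group: BenefitGroup


@dataclass(frozen=True)
class ComplianceResult:
    """Raw-milk standards flags; ``overall`` is the conjunction."""

    scc_ok: bool
    fat_ok: bool
    snf_ok: bool

    @property
    def overall(self) -> bool:
        return self.scc_ok and self.fat_ok and self.snf_ok


@dataclass(frozen=True)
class PaymentSchedule:
    """Ordered payment bands per component, best class first.

    Bands must be non-overlapping and, at the comparison resolution
    (2 decimals for fat/SNF, integer cells/mL for SCC), exhaustive over
    the admissible range.
    """

    bands: Mapping[Component, tuple[PaymentBand, ...]]
    currency: str = "baht_per_1000kg"

    def __post_init__(self) -> None:
        for comp in Component:
            if comp not in self.bands or not self.bands[comp]:
                raise ValueError(f"schedule missing bands for {comp.value}")

    # -- serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "PaymentSchedule":
        bands: dict[Component, tuple[PaymentBand, ...]] = {}
        for comp in Component:
            entries = data.get(comp.value, [])
            bands[comp] = tuple(
                PaymentBand(
                    component=comp,
                    lower=None if e.get("lower") is None else float(e["lower"]),
                    upper=None if e.get("upper") is None else float(e["upper"]),
                    label=str(e["label"]),
                    adjustment=float(e["adjustment"]),
                    usd=None if e.get("usd") is None else float(e["usd"]),
                )
                for e in entries
            )
        return cls(bands=bands, currency=data.get("currency", "baht_per_1000kg"))

    def to_dict(self) -> dict:
        out: dict = {"currency": self.currency}
        for comp in Component:
            out[comp.value] = [
                {
                    "lower": b.lower,
                    "upper": b.upper,
                    "label": b.label,
                    "adjustment": b.adjustment,
                    "usd": b.usd,
                }
                for b in self.bands[comp]
            ]
        return out

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PaymentSchedule":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


_DEFAULT: PaymentSchedule | None = None


def default_schedule() -> PaymentSchedule:
    """The packaged Thai PPBMQ schedule (baht per 1000 kg)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = (
            resources.files("milkpay").joinpath("data/schedule_th2016.yaml").read_text()
        )
        _DEFAULT = PaymentSchedule.from_dict(yaml.safe_load(text))
    return _DEFAULT


def _comparison_value(value: float, component: Component) -> float:
    """Map a raw component value to the schedule's comparison resolution."""
    if component is Component.SCC:
        # thousands of cells/mL -> integer cells/mL
        return float(round(value * 1000.0))
    return _round2(value)


def classify_component(
    value: float,
    component: Component | str,
    schedule: PaymentSchedule | None = None,
) -> ClassAssignment:
    """Assign a single component value to its payment band.

    Fat and SNF are given in percent, SCC in thousands of cells/mL.
    """
    component = Component(component)
    if value < 0:
        raise ValueError(f"negative {component.value} value {value!r} is not admissible")
    schedule = schedule or default_schedule()
    cmp_value = _comparison_value(value, component)
    for band in schedule.bands[component]:
        if band.contains(cmp_value):
            return ClassAssignment(
                component=component,
                label=band.label,
                category=band.category,
                adjustment=band.adjustment,
            )
    raise ValueError(
        f"no payment band covers {component.value}={value!r} "
        f"(compared as {cmp_value}); schedule is not exhaustive"
    )


def score_record(
    record: BTMRecord, schedule: PaymentSchedule | None = None
) -> PaymentResult:
    """Score one BTM record: three class assignments, final price, group."""
    schedule = schedule or default_schedule()
    assignments = {
        Component.FAT: classify_component(record.fat, Component.FAT, schedule),
        Component.SNF: classify_component(record.snf, Component.SNF, schedule),
        Component.SCC: classify_component(record.scc, Component.SCC, schedule),
    }
    fp = sum(a.adjustment for a in assignments.values())
    if fp > 0:
        group = BenefitGroup.GAIN
    elif fp < 0:
        group = BenefitGroup.LOSS
    else:
        group = BenefitGroup.NONE
    return PaymentResult(assignments=assignments, final_price=fp, group=group)


def check_compliance(record: BTMRecord) -> ComplianceResult:
    """Check a record against the Thai raw-milk standards.

    Boundary-inclusive: SCC of exactly 500,000 cells/mL, fat of exactly
    3.35 %, and SNF of exactly 8.25 % all pass.
    """
    return ComplianceResult(
        scc_ok=record.scc <= SCC_LIMIT_THOUSANDS,
        fat_ok=record.fat >= FAT_MINIMUM_PCT,
        snf_ok=record.snf >= SNF_MINIMUM_PCT,
    )


def _vector_classify(
    values: np.ndarray, component: Component, schedule: PaymentSchedule
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized band lookup; returns (labels, categories, adjustments)."""
    if np.any(values < 0):
        bad = np.flatnonzero(values < 0)[:5]
        raise ValueError(
            f"negative {component.value} values at rows {bad.tolist()}"
        )
    if component is Component.SCC:
        cmp_values = np.round(values * 1000.0)
    else:
        cmp_values = np.floor(values * 100.0 + 0.5 + 1e-9) / 100.0
    bands = schedule.bands[component]
    labels = np.full(values.shape, "", dtype=object)
    cats = np.full(values.shape, "", dtype=object)
    adjs = np.full(values.shape, np.nan)
    unassigned = np.ones(values.shape, dtype=bool)
    for band in bands:
        lo = -np.inf if band.lower is None else band.lower
        hi = np.inf if band.upper is None else band.upper
        mask = unassigned & (cmp_values >= lo) & (cmp_values <= hi)
        labels[mask] = band.label
        cats[mask] = band.category.value
        adjs[mask] = band.adjustment
        unassigned &= ~mask
    if unassigned.any():
        bad = np.flatnonzero(unassigned)[:5]
        raise ValueError(
            f"{component.value} values at rows {bad.tolist()} fall outside "
            "every payment band"
        )
    return labels, cats, adjs


def score_panel(
    df: pd.DataFrame, schedule: PaymentSchedule | None = None
) -> pd.DataFrame:
    """Score a whole panel at once.

    Expects columns ``fat_pct``, ``snf_pct``, ``scc_thousand`` and appends
    ``fat_class``, ``snf_class``, ``scc_class``, the matching
    ``*_category`` columns, ``final_price_baht`` and ``benefit_group``.
    Returns a new DataFrame; the input is not modified.
    """
    schedule = schedule or default_schedule()
    out = df.copy()
    total = np.zeros(len(df))
    for comp, col in [
        (Component.FAT, "fat_pct"),
        (Component.SNF, "snf_pct"),
        (Component.SCC, "scc_thousand"),
    ]:
        labels, cats, adjs = _vector_classify(
            df[col].to_numpy(dtype=float), comp, schedule
        )
        out[f"{comp.value}_class"] = labels
        out[f"{comp.value}_category"] = cats
        total += adjs
    out["final_price_baht"] = total
    out["benefit_group"] = np.select(
        [total > 0, total < 0], [BenefitGroup.GAIN.value, BenefitGroup.LOSS.value],
        default=BenefitGroup.NONE.value,
    )
    return out
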