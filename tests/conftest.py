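import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from milkpay.panel import PanelDataset
from milkpay.schedule import score_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(
    fat, snf, scc, region="central", farm_id=None, year=2018, month=None
) -> PanelDataset:
    """Small hand-built panel; vectors are broadcast to a common length."""
    n = max(np.size(fat), np.size(snf), np.size(scc))
    df = pd.DataFrame(
        {
            "farm_id": [f"f{i}" for i in range(n)] if farm_id is None else farm_id,
            "region": region,
            "year": year,
            "month": np.resize(month if month is not None else 1, n),
            "fat_pct": np.resize(fat, n).astype(float),
            "snf_pct": np.resize(snf, n).astype(float),
            "scc_thousand": np.resize(scc, n).astype(float),
        }
    )
    return PanelDataset(df)


def random_scored_panel(rng: np.random.Generator, n_max: int = 100) -> PanelDataset:
    """Random small scored panel spanning both regions and several months."""
    n = int(rng.integers(1, n_max + 1))
    n_farms = int(rng.integers(1, 12))
    farm = rng.integers(0, n_farms, n)
    region_of_farm = rng.integers(0, 2, n_farms)
    year = 2018 + rng.integers(0, 2, n)
    month = rng.integers(1, 13, n)
    df = pd.DataFrame(
        {
            "farm_id": [f"f{i}" for i in farm],
            "region": np.array(["north", "central"])[region_of_farm[farm]],
            "year": year,
            "month": month,
            "fat_pct": np.round(rng.uniform(2.5, 5.0, n), 2),
            "snf_pct": np.round(rng.uniform(7.8, 9.2, n), 2),
            "scc_thousand": np.round(rng.lognormal(5.9, 0.7, n)),
        }
    )
    df = df.drop_duplicates(subset=["farm_id", "year", "month"]).reset_index(drop=True)
    return PanelDataset(score_panel(df))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
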