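"""Reading, writing, and the end-to-end pipeline.

CSV is the single interchange format.  A panel file has a header row and
columns farm_id, region, year, month, fat_pct, snf_pct, scc_thousand;
scoring appends the class/category columns, final_price_baht, and
benefit_group.  ``run_pipeline`` chains simulate (optional) -> score ->
summarize -> patterns -> fit -> contrasts -> report, writing every
intermediate table plus a run log.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glmm import GLMMSpec, fit_glmm, monthly_contrasts, predicted_proportions
from .panel import REQUIRED_COLUMNS, PanelDataset
from .schedule import PaymentSchedule, default_schedule, score_panel
from .summarize import benefit_proportions, category_percentages, top_patterns
from .synthetic import GeneratorParams, default_params, generate_panel

logger = logging.getLogger(__name__)

__all__ = ["read_panel", "write_panel", "PipelineConfig", "run_pipeline"]

_NUMERIC = ["year", "month", "fat_pct", "snf_pct", "scc_thousand"]


def read_panel(path: Union[str, Path]) -> PanelDataset:
    """Read and validate a panel CSV.

    Raises ``ValueError`` listing the offending rows for missing columns,
    non-numeric values, or duplicate (farm_id, year, month) keys.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"farm_id": str, "region": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_rows: list[int] = []
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        bad_rows.extend(bad)
        df[col] = coerced
    na_rows = df.index[df[_NUMERIC].isna().any(axis=1)].tolist()
    bad_rows = sorted(set(bad_rows) | set(na_rows))
    if bad_rows:
        # +2: header line and 1-based numbering, matching the file on disk
        raise ValueError(
            f"{path}: non-numeric or missing values in file rows "
            f"{[r + 2 for r in bad_rows[:10]]}"
        )
    dup = df.duplicated(subset=["farm_id", "year", "month"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (farm_id, year, month) in file rows "
            f"{[r + 2 for r in df.index[dup][:10].tolist()]}"
        )
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    return PanelDataset(df)


def write_panel(data: PanelDataset, path: Union[str, Path]) -> None:
    data.df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    With ``input_path`` unset, a synthetic panel is generated from
    ``generator_params_path`` (or the packaged defaults).  ``seed``
    overrides the generator seed and seeds the contrast adjustment.
    """

    out_dir: Union[str, Path] = "milkpay_out"
    input_path: Union[str, Path, None] = None
    schedule_path: Union[str, Path, None] = None
    generator_params_path: Union[str, Path, None] = None
    top_k: int = 5
    adjustment: str = "single_step_mvn"
    n_quad: int = 15
    seed: int | None = None
    fit_model: bool = True
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("input_path", "schedule_path", "generator_params_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_quad < 2:
            raise ValueError("n_quad must be >= 2")
        if self.adjustment not in {"single_step_mvn", "sidak", "none"}:
            raise ValueError(f"unknown adjustment {self.adjustment!r}")


def _load_schedule(config: PipelineConfig) -> PaymentSchedule:
    if config.schedule_path is not None:
        return PaymentSchedule.from_yaml(config.schedule_path)
    return default_schedule()


def _load_params(config: PipelineConfig) -> GeneratorParams:
    if config.generator_params_path is not None:
        params = GeneratorParams.from_yaml(config.generator_params_path)
    else:
        params = default_params()
    if config.seed is not None:
        from dataclasses import replace

        params = replace(params, seed=config.seed)
    return params


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a name -> path map of written artifacts.

    Any stage failure raises with a stage-named message; the output
    directory is only created after the configuration validates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage = "setup"

    def _write(name: str, df: pd.DataFrame, fname: str) -> None:
        path = out / fname
        df.to_csv(path, index=False, float_format="%.6g")
        artifacts[name] = path

    try:
        t0 = time.perf_counter()
        schedule = _load_schedule(config)

        stage = "simulate" if config.input_path is None else "load"
        if config.input_path is None:
            params = _load_params(config)
            panel = generate_panel(params)
            write_panel(panel, out / "panel.csv")
            artifacts["panel"] = out / "panel.csv"
        else:
            params = None
            panel = read_panel(config.input_path)
        timings[stage] = time.perf_counter() - t0

        stage = "score"
        t0 = time.perf_counter()
        scored = PanelDataset(score_panel(panel.df, schedule))
        _write("scored", scored.df, "scored.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "summarize"
        t0 = time.perf_counter()
        _write(
            "category_percentages",
            category_percentages(scored),
            "category_percentages.csv",
        )
        _write(
            "benefit_by_region",
            benefit_proportions(scored, {"region"}),
            "benefit_by_region.csv",
        )
        _write(
            "benefit_by_region_month",
            benefit_proportions(scored, {"region", "month"}),
            "benefit_by_region_month.csv",
        )
        timings[stage] = time.perf_counter() - t0

        stage = "patterns"
        t0 = time.perf_counter()
        for region in scored.regions:
            _write(
                f"patterns_{region}",
                top_patterns(scored, region, config.top_k),
                f"patterns_{region}.csv",
            )
        timings[stage] = time.perf_counter() - t0

        fit = None
        if config.fit_model and len(scored.regions) == 2 and scored.n_months >= 2:
            stage = "fit"
            t0 = time.perf_counter()
            fit = fit_glmm(scored, GLMMSpec(n_quad=config.n_quad))
            coef = fit.beta.rename("estimate").to_frame()
            if fit.vcov is not None:
                coef["se"] = np.sqrt(np.diag(fit.vcov.to_numpy()))
            _write("glmm_coefficients", coef.reset_index(names="coefficient"),
                   "glmm_coefficients.csv")
            (out / "glmm_summary.txt").write_text(fit.summary() + "\n")
            artifacts["glmm_summary"] = out / "glmm_summary.txt"
            _write(
                "predicted_proportions",
                predicted_proportions(fit),
                "predicted_proportions.csv",
            )
            timings[stage] = time.perf_counter() - t0

            stage = "contrasts"
            t0 = time.perf_counter()
            contrasts = monthly_contrasts(
                fit,
                adjustment=config.adjustment,
                seed=0 if config.seed is None else config.seed,
            )
            _write("contrasts", contrasts, "contrasts.csv")
            timings[stage] = time.perf_counter() - t0

        stage = "report"
        t0 = time.perf_counter()
        if config.make_plots:
            from .plots import save_report_plots

            artifacts.update(save_report_plots(scored, out))
        log = {
            "milkpay_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "generator_params": None if params is None else params.to_dict(),
            "config": {
                k: str(v) if isinstance(v, Path) else v
                for k, v in vars(config).items()
            },
            "n_records": scored.n_records,
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
        artifacts["run_log"] = out / "run_log.json"
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    for name, seconds in timings.items():
        logger.info("stage %-10s %.2fs", name, seconds)
    return artifacts
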