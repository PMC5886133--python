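"""End-to-end orchestration: panel in, gap and allocation tables out.

Chains the stages — mortality regression, expected-trend projection,
required trajectory and need, expected spending, potential spending (DEA),
gaps, allocation and rankings — and writes one CSV per stage plus a JSON
run manifest. High-income countries are dropped from the case-study
pipeline because the cost-per-life-saved schedule defines no high-income
cost.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .allocation import (
    RANK_CRITERIA,
    allocate,
    allocation_to_frame,
    compute_gaps,
    gaps_to_frame,
    rank_countries,
)
from .errors import FgapsError
from .expected_spend import es_to_frame, fit_fraction_model, forecast_expected_spend
from .mortality import fit_mortality_model, project_expected_trend, trends_to_frame
from .need import compute_need, lives_to_save, need_to_frame, required_trajectory
from .panel import CountryYearPanel, RunConfig, read_panel
from .potential_spend import fit_frontier, forecast_potential_spend, ps_to_frame

log = logging.getLogger("fgaps")


class StageError(FgapsError):
    """A pipeline stage failed; names the stage for the CLI exit message."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage} failed: {cause}")


@dataclass
class RunOutputs:
    """In-memory results of a full pipeline run."""

    trends: pd.DataFrame
    need: pd.DataFrame
    es: pd.DataFrame
    ps: pd.DataFrame
    gaps: pd.DataFrame
    alloc: pd.DataFrame
    ranks: dict[str, pd.DataFrame]
    top_need: pd.DataFrame


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def top_need_table(need_df: pd.DataFrame, gaps_df: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k countries with the largest need, with gap percentages.

    Gap A is reported as a share of need, 100 * (N - PS) / N; Gap B as a
    share of potential, 100 * (PS - ES) / PS.
    """
    totals = need_df.drop_duplicates("country_id")[
        ["country_id", "lives_total", "unit_cost", "need_usd"]
    ]
    if k > len(totals):
        raise FgapsError(f"k = {k} exceeds the {len(totals)} available countries")
    merged = totals.merge(gaps_df, on="country_id", suffixes=("", "_g"))
    merged = merged.sort_values(
        ["need_usd", "country_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    merged["gap_a_pct_of_need"] = 100.0 * merged["gap_a"] / merged["need_usd"]
    merged["gap_b_pct_of_potential"] = 100.0 * merged["gap_b"] / merged["ps_usd"]
    cols = ["country_id", "need_usd", "es_usd", "ps_usd", "gap_a", "gap_b",
            "gap_a_pct_of_need", "gap_b_pct_of_potential", "lives_total", "unit_cost"]
    return merged[cols].reset_index(drop=True)


def run_pipeline(
    panel: CountryYearPanel,
    subaccounts: pd.DataFrame,
    config: RunConfig,
    top_k: int | None = 10,
) -> RunOutputs:
    """Run every stage on in-memory inputs and return the stage tables."""
    base_year = config.resolve_base_year(panel)

    high = [c for c in panel.countries if panel.income_group_of(c) == "high"]
    if high:
        log.info("dropping %d high-income countries (no unit cost): %s",
                 len(high), high)
        panel = CountryYearPanel.from_dataframe(
            panel.df[~panel.df["country_id"].isin(high)]
        )

    log.info("stage fit-mortality: %d observed rows", len(panel.observed()))
    model = fit_mortality_model(panel, base_year=base_year)
    log.info("stage forecast: projecting expected trends to %d",
             config.goal_target_year)
    trends = project_expected_trend(model, panel, config)

    log.info("stage need")
    need_results = []
    for t in trends:
        cdf = panel.country(t.country_id).set_index("year")
        baseline = float(cdf.loc[base_year, "u5mr"])
        req = required_trajectory(baseline, config, t)
        lives = lives_to_save(t, req, panel, config)
        need_results.append(
            compute_need(lives, panel.income_group_of(t.country_id), config,
                         country_id=t.country_id)
        )

    log.info("stage expected-spend: %d sub-account rows", len(subaccounts))
    frac_model = fit_fraction_model(subaccounts, link=config.fraction_link)
    es_results = forecast_expected_spend(frac_model, panel, config)

    log.info("stage potential-spend: DEA frontier at %d", base_year)
    frontier = fit_frontier(panel, base_year)
    ps_results = forecast_potential_spend(frontier, frac_model, panel, config)

    log.info("stage gaps")
    gaps = compute_gaps(need_results, es_results, ps_results)
    log.info("stage allocate")
    allocs = allocate(gaps, config)
    ranks = {c: rank_countries(panel, gaps, c) for c in RANK_CRITERIA}

    need_df = need_to_frame(need_results)
    gaps_df = gaps_to_frame(gaps)
    k = min(top_k or len(gaps), len(gaps))
    return RunOutputs(
        trends=trends_to_frame(trends),
        need=need_df,
        es=es_to_frame(es_results),
        ps=ps_to_frame(ps_results),
        gaps=gaps_df,
        alloc=allocation_to_frame(allocs),
        ranks=ranks,
        top_need=top_need_table(need_df, gaps_df, k),
    )


def run_all(
    config: RunConfig,
    panel_path,
    subaccounts_path,
    out_dir,
    top_k: int = 10,
) -> Path:
    """File-based end-to-end run; writes stage CSVs and manifest.json.

    Any stage failure raises with the stage named, after logging it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel_path = Path(panel_path)
    subaccounts_path = Path(subaccounts_path)

    stage = "read-panel"
    try:
        panel = read_panel(panel_path)
        # The sub-accounts file belongs to the expected-spend stage.
        stage = "expected-spend"
        if not subaccounts_path.exists():
            raise FgapsError(f"subaccounts file not found: {subaccounts_path}")
        subaccounts = pd.read_csv(subaccounts_path)
        stage = "pipeline"
        out = run_pipeline(panel, subaccounts, config, top_k=top_k)
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    out.trends.to_csv(out_dir / "trends.csv", index=False)
    out.need.to_csv(out_dir / "need.csv", index=False)
    out.es.to_csv(out_dir / "es.csv", index=False)
    out.ps.to_csv(out_dir / "ps.csv", index=False)
    out.gaps.to_csv(out_dir / "gaps.csv", index=False)
    out.alloc.to_csv(out_dir / "alloc.csv", index=False)
    for crit, df in out.ranks.items():
        df.to_csv(out_dir / f"ranks_{crit}.csv", index=False)
    out.top_need.to_csv(out_dir / "top_need.csv", index=False)

    manifest = {
        "fgaps_version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {
            "panel": {"path": str(panel_path), "sha256": _sha256(panel_path)},
            "subaccounts": {
                "path": str(subaccounts_path),
                "sha256": _sha256(subaccounts_path),
            },
        },
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
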