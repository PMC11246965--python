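"""End-to-end orchestration: cohort -> suitability -> scenarios -> scores.

The library modules are independently usable; this module wires them
into the standard run the command-line interface and the reproduction
script share: generate (or load) a plot cohort, annotate occurrence
probabilities with binary and relative suitability, apply the five
species-change scenarios for a future period, score every plot for the
four ecosystem services, and summarize per zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from forest_adapt.inventory import PlotRecord, write_outputs, zone_summary
from forest_adapt.registry import SpeciesRegistry, load_registry
from forest_adapt.scenarios import ScenarioOutcome, run_all
from forest_adapt.services import scores_frame
from forest_adapt.suitability import build_suitability_table
from forest_adapt.synthetic import GeneratorConfig, generate_plots, generate_suitability

__all__ = ["PipelineResult", "run_synthetic_pipeline", "score_period"]

RCP_PERIODS = {"4.5": "rcp45_2081_2100", "8.5": "rcp85_2081_2100"}


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    plots: list[PlotRecord]
    suitability: pd.DataFrame
    period: str
    outcomes: dict[str, list[ScenarioOutcome]]
    scores: pd.DataFrame
    zones: pd.DataFrame
    n_dropped_sites: int = 0
    subplots: pd.DataFrame | None = None


def score_period(
    plots: Sequence[PlotRecord],
    suitability: pd.DataFrame,
    period: str,
    registry: SpeciesRegistry | None = None,
    no_adaptation_redistribution: str = "proportional",
    weighted_production: bool = False,
) -> tuple[dict[str, list[ScenarioOutcome]], pd.DataFrame, pd.DataFrame]:
    """Scenarios, per-plot scores and zone summaries for one future period."""
    registry = registry or load_registry()
    outcomes = run_all(plots, suitability, period, registry, no_adaptation_redistribution)
    scores = scores_frame(plots, outcomes, registry, weighted_production=weighted_production)
    zones = zone_summary(scores)
    return outcomes, scores, zones


def run_synthetic_pipeline(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    rcp: str = "8.5",
    registry: SpeciesRegistry | None = None,
    out_dir: str | Path | None = None,
    no_adaptation_redistribution: str = "proportional",
) -> PipelineResult:
    """Run the full analysis on a synthetic cohort.

    ``rcp`` is "4.5" or "8.5" and selects the 2081-2100 future period.
    When ``out_dir`` is given, the plot table, suitability table,
    per-plot scores, zone summary and change GeoJSON layers are written
    there.
    """
    registry = registry or load_registry()
    config = config or GeneratorConfig()
    if rcp not in RCP_PERIODS:
        raise ValueError(f"unknown RCP {rcp!r}; expected one of {sorted(RCP_PERIODS)}")
    period = RCP_PERIODS[rcp]

    subplots, plots, dropped = generate_plots(config, seed=seed, registry=registry)
    raw = generate_suitability(plots, config, seed=seed + 1)
    suitability = build_suitability_table(raw, registry)
    outcomes, scores, zones = score_period(
        plots,
        suitability,
        period,
        registry,
        no_adaptation_redistribution=no_adaptation_redistribution,
    )

    result = PipelineResult(plots, suitability, period, outcomes, scores, zones, dropped, subplots)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from forest_adapt.inventory import write_plots

        write_plots(plots, out_dir / "plots.csv", registry)
        suitability.to_csv(out_dir / "suitability.csv", index=False)
        write_outputs(scores, out_dir, plots=plots)
    return result
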