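"""Ecosystem-service scoring of current and post-scenario plots.

Four services are quantified per plot:

* **Timber productivity** — the mean standardized annual increment of
  the species present, binned into high (> 0.78), moderate (0.63–0.78)
  and low (< 0.63) production.  The band edges correspond to the most
  and least productive native species.
* **Tree-species richness** — the count of taxa with a positive share.
* **Non-native share** — the summed share of non-native taxa relative
  to the total stocked share.
* **Protection** against avalanches and rockfall, as ordinal risk
  categories (high / moderate / low).  Avalanche risk applies only to
  plots above 800 m with slopes of 25–60 degrees and is driven by the
  wintergreen (evergreen) canopy share, with a stand-volume floor of
  100 m³ ha⁻¹ below which the stand is considered not fully stocked and
  risk is high regardless of composition.  Rockfall risk applies only to
  plots inside mapped rockfall hazard zones and is driven by stand
  volume alone (>= 360 low, <= 180 high).

Unstocked plots score production 0 (low), richness 0, non-native share
0, and high risk for both protective services: a bare slope protects
nothing.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from forest_adapt.registry import SpeciesRegistry

__all__ = [
    "PRODUCTION_CATEGORIES",
    "RISK_CATEGORIES",
    "RISK_ORDER",
    "production_value",
    "classify_production",
    "richness",
    "nnt_share",
    "frequency_of_occurrence",
    "avalanche_eligible",
    "avalanche_risk",
    "rockfall_risk",
    "change_vs_current",
    "score_outcome",
    "score_current",
    "scores_frame",
]

PRODUCTION_CATEGORIES = ("low", "moderate", "high")
RISK_CATEGORIES = ("high", "moderate", "low", "not_eligible")

#: ordinal scale for risk comparisons: larger is better (safer)
RISK_ORDER = {"high": 0, "moderate": 1, "low": 2}

# production band edges: > HIGH_EDGE is high, < LOW_EDGE is low,
# the closed interval between is moderate
_LOW_EDGE = 0.63
_HIGH_EDGE = 0.78

# avalanche rule constants
_MIN_ALTITUDE_M = 800.0
_SLOPE_RANGE_DEG = (25.0, 60.0)
_MIN_STOCKED_VOLUME = 100.0  # m3/ha; below: not fully stocked, high risk
_WINTERGREEN_LOW_RISK = 0.70
_WINTERGREEN_HIGH_RISK = 0.40

# rockfall volume thresholds, m3 over bark / ha
_ROCKFALL_LOW_RISK = 360.0
_ROCKFALL_HIGH_RISK = 180.0


def _shares_of(outcome) -> dict[str, float]:
    shares = outcome.shares if hasattr(outcome, "shares") else dict(outcome)
    return {s: v for s, v in shares.items() if v > 0}


def production_value(outcome, registry: SpeciesRegistry, weighted: bool = False) -> float:
    """Mean standardized increment over the species present (0 if unstocked).

    The default is the unweighted mean over present species; with
    ``weighted=True`` species are weighted by their stand share.
    """
    shares = _shares_of(outcome)
    if not shares:
        return 0.0
    if weighted:
        total = sum(shares.values())
        return sum(registry.get(s).increment_std * v for s, v in shares.items()) / total
    return sum(registry.get(s).increment_std for s in shares) / len(shares)


def classify_production(value: float) -> str:
    """Production category: high > 0.78, moderate in [0.63, 0.78], low < 0.63."""
    if value < 0:
        raise ValueError(f"production value must be >= 0, got {value}")
    if value > _HIGH_EDGE:
        return "high"
    if value >= _LOW_EDGE:
        return "moderate"
    return "low"


def richness(outcome) -> int:
    """Number of taxa with a positive share (merged oaks count once)."""
    return len(_shares_of(outcome))


def nnt_share(outcome, registry: SpeciesRegistry) -> float:
    """Summed non-native share over total stocked share (0 if unstocked)."""
    shares = _shares_of(outcome)
    total = sum(shares.values())
    if total == 0:
        return 0.0
    nnt = sum(v for s, v in shares.items() if not registry.get(s).native)
    return nnt / total


def frequency_of_occurrence(outcomes: Sequence, species: str) -> float:
    """Percent of plots on which the species has a positive share."""
    if len(outcomes) == 0:
        raise ValueError("no plots")
    n_with = sum(1 for o in outcomes if _shares_of(o).get(species, 0.0) > 0)
    return 100.0 * n_with / len(outcomes)


def avalanche_eligible(plot) -> bool:
    """Avalanche risk is assessed above 800 m on slopes of 25-60 degrees."""
    return plot.altitude > _MIN_ALTITUDE_M and _SLOPE_RANGE_DEG[0] <= plot.slope <= _SLOPE_RANGE_DEG[1]


def wintergreen_share(outcome, registry: SpeciesRegistry) -> float:
    """Evergreen-canopy fraction of the stocked share (0 if unstocked)."""
    shares = _shares_of(outcome)
    total = sum(shares.values())
    if total == 0:
        return 0.0
    wg = sum(v for s, v in shares.items() if registry.get(s).evergreen)
    return wg / total


def avalanche_risk(outcome, registry: SpeciesRegistry, volume: float | None = None) -> str:
    """Avalanche risk category for an eligible plot.

    High if the stand volume is at most 100 m³ ha⁻¹ (not fully stocked)
    or the wintergreen share is at most 40 %; low if the wintergreen
    share is at least 70 % (and the stand is stocked); moderate
    otherwise.  Unstocked plots are high risk.
    """
    vol = outcome.volume if volume is None else volume
    shares = _shares_of(outcome)
    if not shares or vol <= _MIN_STOCKED_VOLUME:
        return "high"
    wg = wintergreen_share(outcome, registry)
    if wg <= _WINTERGREEN_HIGH_RISK:
        return "high"
    if wg >= _WINTERGREEN_LOW_RISK:
        return "low"
    return "moderate"


def rockfall_risk(outcome, volume: float | None = None) -> str:
    """Rockfall risk from stand volume: low >= 360, high <= 180, else moderate."""
    vol = outcome.volume if volume is None else volume
    shares = _shares_of(outcome)
    if not shares or vol <= _ROCKFALL_HIGH_RISK:
        return "high"
    if vol >= _ROCKFALL_LOW_RISK:
        return "low"
    return "moderate"


def change_vs_current(current, scenario, kind: str = "numeric") -> tuple[int, float | None]:
    """Signed change of a scenario score against the current score.

    ``kind='numeric'`` compares numbers and also returns the percent
    change 100 x (scenario - current) / current (None when the current
    value is 0 and the scenario value is not, which has no percent
    representation).  ``kind='risk'`` compares ordinal risk categories,
    where a move towards lower risk is an improvement (+1); the percent
    slot is None.
    """
    if kind == "risk":
        if current not in RISK_ORDER or scenario not in RISK_ORDER:
            raise ValueError(f"not comparable risk categories: {current!r}, {scenario!r}")
        diff = RISK_ORDER[scenario] - RISK_ORDER[current]
        return (0 if diff == 0 else (1 if diff > 0 else -1)), None
    cur, sce = float(current), float(scenario)
    sign = 0 if sce == cur else (1 if sce > cur else -1)
    if cur == 0:
        return sign, (0.0 if sce == 0 else None)
    return sign, 100.0 * (sce - cur) / cur


def score_outcome(outcome, plot, registry: SpeciesRegistry, weighted_production: bool = False) -> dict:
    """All service scores for one plot outcome (current or post-scenario)."""
    value = production_value(outcome, registry, weighted=weighted_production)
    scores = {
        "plot_id": plot.plot_id,
        "zone": plot.zone,
        "production_value": value,
        "production_category": classify_production(value),
        "richness": richness(outcome),
        "nnt_share": nnt_share(outcome, registry),
        "volume": outcome.volume,
        "unstocked": bool(getattr(outcome, "unstocked", sum(_shares_of(outcome).values()) == 0)),
    }
    scores["avalanche_risk"] = (
        avalanche_risk(outcome, registry) if avalanche_eligible(plot) else "not_eligible"
    )
    scores["rockfall_risk"] = rockfall_risk(outcome) if plot.rockfall_zone else "not_eligible"
    return scores


class _CurrentOutcome:
    """Adapter presenting a plot's present composition as an outcome."""

    __slots__ = ("shares", "volume", "unstocked")

    def __init__(self, plot):
        self.shares = {s: v for s, v in plot.shares.items() if v > 0}
        self.volume = plot.volume
        self.unstocked = sum(self.shares.values()) == 0


def score_current(plot, registry: SpeciesRegistry, weighted_production: bool = False) -> dict:
    """Service scores for the present-day composition of a plot."""
    return score_outcome(_CurrentOutcome(plot), plot, registry, weighted_production)


def scores_frame(
    plots: Sequence,
    results: Mapping[str, Sequence],
    registry: SpeciesRegistry,
    include_current: bool = True,
    weighted_production: bool = False,
) -> pd.DataFrame:
    """Per-plot score table over scenarios, with signed change vs current.

    ``results`` maps scenario label -> outcomes aligned with ``plots``.
    The current state is scored under the label ``current``.  Change
    columns (-1/0/+1) are added for production value, richness and both
    risk services; risk changes are blank for ineligible plots.
    """
    by_id = {p.plot_id: p for p in plots}
    rows: list[dict] = []
    current_scores = {p.plot_id: score_current(p, registry, weighted_production) for p in plots}
    if include_current:
        for p in plots:
            row = dict(current_scores[p.plot_id])
            row["scenario"] = "current"
            for svc in ("production", "richness", "nnt_share", "avalanche", "rockfall", "volume"):
                row[f"change_{svc}"] = 0
            rows.append(row)
    for label, outcomes in results.items():
        for o in outcomes:
            plot = by_id[o.plot_id]
            row = score_outcome(o, plot, registry, weighted_production)
            row["scenario"] = label
            cur = current_scores[o.plot_id]
            row["change_production"], _ = change_vs_current(cur["production_value"], row["production_value"])
            row["change_richness"], _ = change_vs_current(cur["richness"], row["richness"])
            row["change_nnt_share"], _ = change_vs_current(cur["nnt_share"], row["nnt_share"])
            row["change_volume"], _ = change_vs_current(cur["volume"], row["volume"])
            for svc, key in (("avalanche", "avalanche_risk"), ("rockfall", "rockfall_risk")):
                if row[key] == "not_eligible":
                    row[f"change_{svc}"] = 0
                else:
                    row[f"change_{svc}"], _ = change_vs_current(cur[key], row[key], kind="risk")
            rows.append(row)
    df = pd.DataFrame(rows)
    lead = ["plot_id", "zone", "scenario"]
    return df[lead + [c for c in df.columns if c not in lead]]
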