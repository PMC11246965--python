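"""Rule-based species-change scenarios for a future climate period.

Five scenarios describe how the growing space vacated by locally failing
species (present today, climatically unsuitable in the future period) is
refilled:

``no_adaptation``
    No active adaptation: a failing species can only be replaced by
    species that already occur at the plot and remain suitable.  By
    default its share is redistributed over those survivors in proportion
    to their current shares, while the stand volume is reduced by the
    failing species' share — composition persists but standing stock is
    lost.  If no resident survives, the plot is left unstocked.
``native_mss`` / ``combi_mss``
    Replace each failing species with the most suitable species (MSS):
    the candidate with the highest relative suitability, drawn from the
    native-only pool (``native``) or from all fifteen taxa (``combi``).
``native_ccbb`` / ``combi_ccbb``
    Conifer-for-conifer / broadleaf-for-broadleaf (CC/BB): prefer the
    most suitable candidate of the same growth form as the failing
    species; if no same-form candidate is suitable, fall back to the
    overall most suitable species.

Adaptation scenarios transfer the failing species' share *and* its
volume to the receiver (merging with an existing share if the receiver
is already present); a failing species that finds no suitable receiver
loses both, and a plot where nothing remains is unstocked.

Ties in relative suitability break deterministically: higher
standardized increment first, then lexicographically smaller code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from forest_adapt.registry import SpeciesRegistry
from forest_adapt.suitability import failing_species

__all__ = [
    "ScenarioSpec",
    "ScenarioOutcome",
    "Replacement",
    "SCENARIOS",
    "SCENARIO_LABELS",
    "select_replacement",
    "apply_scenario",
    "run_all",
]

#: label -> (candidate pool, replacement strategy)
SCENARIOS: dict[str, tuple[str, str]] = {
    "no_adaptation": ("resident", "none"),
    "native_mss": ("native", "mss"),
    "combi_mss": ("combi", "mss"),
    "native_ccbb": ("native", "ccbb"),
    "combi_ccbb": ("combi", "ccbb"),
}

SCENARIO_LABELS = tuple(SCENARIOS)


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the five species-change scenarios bound to a future period."""

    label: str
    period: str

    def __post_init__(self) -> None:
        if self.label not in SCENARIOS:
            raise ValueError(f"unknown scenario label: {self.label!r} (expected one of {SCENARIO_LABELS})")

    @property
    def pool(self) -> str:
        return SCENARIOS[self.label][0]

    @property
    def strategy(self) -> str:
        return SCENARIOS[self.label][1]


@dataclass(frozen=True)
class Replacement:
    """One share transfer: failing species -> receiver (or dropped)."""

    failed: str
    receiver: str | None
    share: float


@dataclass
class ScenarioOutcome:
    """Post-scenario composition and stand volume of one plot."""

    plot_id: str
    scenario: str
    period: str
    shares: dict[str, float]
    volume: float
    unstocked: bool
    replacements: list[Replacement] = field(default_factory=list)

    @property
    def total_share(self) -> float:
        return sum(self.shares.values())


def _suitability_maps(table, period: str | None) -> tuple[dict[str, bool], dict[str, float]]:
    if isinstance(table, pd.DataFrame):
        sub = table if period is None else table.loc[table["period"] == period]
        return (
            dict(zip(sub["species"], sub["suitable"])),
            dict(zip(sub["species"], sub["relative"])),
        )
    # mapping species -> (suitable, relative)
    return ({s: v[0] for s, v in table.items()}, {s: v[1] for s, v in table.items()})


def select_replacement(
    failing: str,
    candidates: Mapping[str, float],
    spec: ScenarioSpec,
    registry: SpeciesRegistry,
) -> str | None:
    """Pick the receiver for one failing species, or None.

    ``candidates`` maps species code -> relative suitability for the
    species in the scenario's pool; only suitable candidates (relative
    >= 1) are considered, and the failing species never replaces itself.
    MSS takes the overall argmax of relative suitability; CC/BB
    restricts to the failing species' growth form first and falls back
    to the overall argmax if that subset is empty.  Returns None when no
    candidate is suitable.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    pool = {c: r for c, r in candidates.items() if c != failing and r >= 1.0}
    if not pool:
        return None

    def best(codes: dict[str, float]) -> str:
        # ties: higher relative, then higher standardized increment, then code
        return min(
            codes,
            key=lambda c: (-codes[c], -registry.get(c).increment_std, c),
        )

    if spec.strategy == "ccbb":
        failing_conifer = registry.get(failing).conifer
        same_form = {c: r for c, r in pool.items() if registry.get(c).conifer == failing_conifer}
        if same_form:
            return best(same_form)
    return best(pool)


def apply_scenario(
    plot,
    table,
    spec: ScenarioSpec,
    registry: SpeciesRegistry,
    no_adaptation_redistribution: str = "proportional",
) -> ScenarioOutcome:
    """Apply one species-change scenario to one plot.

    ``plot`` is anything with ``plot_id``, ``shares`` (species -> fraction)
    and ``volume`` attributes; ``table`` is a suitability frame (long
    format, filtered to ``spec.period`` internally) or a mapping
    species -> (suitable, relative).

    Surviving suitable residents keep their shares; each failing species'
    share moves according to the scenario rules above.  Volume follows
    the share of stock that keeps a standing species: it is reduced by
    the (relative) share of failing species whose stock is lost — all of
    it under ``no_adaptation``, only receiver-less shares under the
    adaptation scenarios.
    """
    if no_adaptation_redistribution not in ("proportional", "drop"):
        raise ValueError(f"unknown redistribution mode: {no_adaptation_redistribution!r}")

    shares = {s: float(v) for s, v in plot.shares.items() if v > 0}
    total = sum(shares.values())
    if total == 0:
        return ScenarioOutcome(plot.plot_id, spec.label, spec.period, {}, 0.0, True, [])

    suitable_map, relative_map = _suitability_maps(table, spec.period)
    failing = failing_species(shares, suitable_map)
    survivors = {s: shares[s] for s in shares if s not in failing}

    replacements: list[Replacement] = []
    if spec.strategy == "none":
        surv_total = sum(survivors.values())
        new_shares = dict(survivors)
        for f in sorted(failing):
            if surv_total > 0 and no_adaptation_redistribution == "proportional":
                for s in survivors:
                    piece = shares[f] * survivors[s] / surv_total
                    new_shares[s] += piece
                    replacements.append(Replacement(f, s, piece))
            else:
                replacements.append(Replacement(f, None, shares[f]))
        # stock of every failing species is lost even when its growing
        # space is recolonized by residents
        volume = plot.volume * (surv_total / total)
    else:
        if spec.pool == "native":
            pool_codes = set(registry.native_codes)
        else:
            pool_codes = set(registry.codes)
        candidates = {c: relative_map[c] for c in pool_codes if c in relative_map}
        new_shares = dict(survivors)
        lost_share = 0.0
        for f in sorted(failing):
            receiver = select_replacement(f, candidates, spec, registry) if candidates else None
            if receiver is None:
                lost_share += shares[f]
                replacements.append(Replacement(f, None, shares[f]))
            else:
                new_shares[receiver] = new_shares.get(receiver, 0.0) + shares[f]
                replacements.append(Replacement(f, receiver, shares[f]))
        volume = plot.volume * ((total - lost_share) / total)

    new_shares = {s: v for s, v in new_shares.items() if v > 0}
    unstocked = sum(new_shares.values()) == 0
    if unstocked:
        volume = 0.0
    return ScenarioOutcome(plot.plot_id, spec.label, spec.period, new_shares, volume, unstocked, replacements)


def run_all(
    plots,
    table: pd.DataFrame,
    period: str,
    registry: SpeciesRegistry,
    no_adaptation_redistribution: str = "proportional",
) -> dict[str, list[ScenarioOutcome]]:
    """Evaluate all five scenarios for every plot under one future period."""
    if isinstance(table, pd.DataFrame):
        if period not in set(table["period"]):
            raise ValueError(f"suitability table has no rows for period {period!r}")
        sub = table.loc[table["period"] == period]
        per_plot = {
            pid: {s: (bool(su), float(r)) for s, su, r in zip(g["species"], g["suitable"], g["relative"])}
            for pid, g in sub.groupby("plot_id", sort=False)
        }
    else:
        per_plot = table

    results: dict[str, list[ScenarioOutcome]] = {}
    for label in SCENARIO_LABELS:
        spec = ScenarioSpec(label, period)
        outcomes = []
        for plot in plots:
            plot_table = per_plot.get(plot.plot_id, {})
            outcomes.append(
                apply_scenario(plot, plot_table, spec, registry, no_adaptation_redistribution)
            )
        results[label] = outcomes
    return results


def outcomes_to_frame(results: Mapping[str, list[ScenarioOutcome]]) -> pd.DataFrame:
    """Long-format export: one row per plot x scenario x species."""
    rows = []
    for label, outcomes in results.items():
        for o in outcomes:
            if o.shares:
                for s, v in sorted(o.shares.items()):
                    rows.append((o.plot_id, label, o.period, s, v, o.volume, o.unstocked))
            else:
                rows.append((o.plot_id, label, o.period, "", 0.0, o.volume, o.unstocked))
    return pd.DataFrame(
        rows,
        columns=["plot_id", "scenario", "period", "species", "share", "volume", "unstocked"],
    )
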