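"""Seeded generator of inventory-like plot sets and suitability tables.

Real national forest-inventory coordinates are confidential, so the
package ships a generator that emulates the statistical structure the
analysis assumes: survey sites of four subplots aggregated to centroids,
zone-stratified terrain (Alpine South high and steep, Pannonian low and
flat), compositional species shares drawn from zone-specific mixture
priors (spruce-dominated in the mountains, oak/pine with a sizeable
non-native admixture in the Pannonian lowland), right-skewed lognormal
stand volumes in the observed 0–1700 m³ ha⁻¹ range, and per-species
occurrence probabilities built mechanistically as logistic functions of
altitude with period-specific shifts — montane species retreat uphill
under warming while thermophilous species expand, so monotonicity in the
climate-impact knob holds by construction.

Default sizes mirror the study region: 1423 Alpine South, 1448
Continental and 150 Pannonian sites.  Everything is reproducible from a
single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from forest_adapt.inventory import PlotRecord, aggregate_subplots
from forest_adapt.registry import SpeciesRegistry, load_registry

__all__ = [
    "ZoneTerrain",
    "SpeciesClimate",
    "GeneratorConfig",
    "generate_plots",
    "generate_suitability",
    "scenario_fixture",
    "expected_avalanche_fraction",
    "expected_rockfall_fraction",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class ZoneTerrain:
    """Normal terrain model of one environmental zone (site level)."""

    altitude_mean: float  # m a.s.l.
    altitude_sd: float
    slope_mean: float     # degrees
    slope_sd: float
    volume_mean: float    # m3 over bark / ha (lognormal mean)
    rockfall_p: float     # probability a site lies in a rockfall hazard zone
    lon: tuple[float, float]
    lat: tuple[float, float]


@dataclass(frozen=True)
class SpeciesClimate:
    """Altitude-logistic occurrence-probability model for one species.

    ``direction`` +1 marks montane species whose suitability rises with
    altitude (logistic midpoint shifts uphill by ``shift`` m per unit of
    climate impact, so low-altitude plots lose suitability); -1 marks
    thermophilous species suitable below the midpoint (an uphill shift
    expands them).  ``decline`` in [0, 1) shrinks the amplitude per
    impact unit, lowering the probability everywhere.
    """

    direction: int
    midpoint: float   # m a.s.l.
    scale: float      # m
    amplitude: float  # percent, peak probability
    shift: float      # m uphill per impact unit
    decline: float = 0.0

    def probability(self, altitude: float | np.ndarray, impact: float) -> np.ndarray:
        mid = self.midpoint + self.shift * impact
        amp = self.amplitude * (1.0 - self.decline) ** impact
        z = (np.asarray(altitude, dtype=float) - mid) / self.scale
        if self.direction >= 0:
            return amp / (1.0 + np.exp(-z))
        return amp / (1.0 + np.exp(z))


_DEFAULT_TERRAIN: dict[str, ZoneTerrain] = {
    "alpine_south": ZoneTerrain(1300, 400, 30, 12, 360, 0.26, (9.5, 15.0), (46.4, 47.8)),
    "continental": ZoneTerrain(650, 300, 15, 10, 370, 0.107, (13.0, 17.0), (47.5, 49.0)),
    "pannonian": ZoneTerrain(250, 80, 4, 3, 280, 0.0, (16.0, 17.2), (47.0, 48.3)),
}

# Zone-specific species-mixture weights (sum to 1 per zone).  Non-native
# weights sum to ~0.01 in the mountain/continental zones and ~0.16 in
# the Pannonian, matching the qualitative admixture levels the analysis
# targets.
_DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    "alpine_south": {
        "pab": 0.55, "lde": 0.12, "fsy": 0.12, "aal": 0.10, "psy": 0.08, "que": 0.02,
        "pme": 0.006, "jni": 0.002, "rps": 0.002,
    },
    "continental": {
        "pab": 0.40, "fsy": 0.25, "psy": 0.12, "lde": 0.08, "que": 0.08, "aal": 0.06,
        "pme": 0.006, "jni": 0.002, "rps": 0.002,
    },
    "pannonian": {
        "que": 0.34, "psy": 0.20, "pab": 0.15, "fsy": 0.10, "lde": 0.03, "aal": 0.02,
        "rps": 0.08, "jni": 0.04, "pme": 0.02, "qru": 0.01, "fpe": 0.01,
    },
}

# Altitude-logistic parameters per modelled species (the two white oaks
# are modelled separately and merged downstream).  Montane natives
# retreat uphill; thermophilous oaks and several NNT expand; four NNT
# have peak probabilities below their cut-offs and are never suitable,
# mirroring their marginal role.
_DEFAULT_CLIMATE: dict[str, SpeciesClimate] = {
    "pab": SpeciesClimate(+1, 600, 150, 95, 350),
    "aal": SpeciesClimate(+1, 700, 150, 90, 300),
    "lde": SpeciesClimate(+1, 900, 150, 90, 350),
    "fsy": SpeciesClimate(+1, 450, 150, 88, 300),
    "psy": SpeciesClimate(-1, 1200, 200, 85, 100, decline=0.25),
    "qpe": SpeciesClimate(-1, 900, 200, 80, 400),
    "qro": SpeciesClimate(-1, 850, 200, 78, 400),
    "pme": SpeciesClimate(-1, 800, 200, 85, 400),
    "jni": SpeciesClimate(-1, 500, 150, 75, 400),
    "rps": SpeciesClimate(-1, 400, 150, 72, 150, decline=0.15),
    "pra": SpeciesClimate(-1, 300, 150, 60, 500),
    "agr": SpeciesClimate(-1, 600, 150, 63, 200),
    "tpl": SpeciesClimate(-1, 600, 150, 54, 200),
    "pco": SpeciesClimate(+1, 900, 200, 60, 100),
    "fpe": SpeciesClimate(-1, 400, 150, 55, 200),
    "qru": SpeciesClimate(-1, 500, 150, 58, 300),
}

#: climate-impact units per period; 0 reproduces the historical surface
_DEFAULT_IMPACTS: dict[str, float] = {
    "historical_1961_1990": 0.0,
    "rcp45_2081_2100": 1.0,
    "rcp85_2081_2100": 2.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunables of the synthetic cohort."""

    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {"alpine_south": 1423, "continental": 1448, "pannonian": 150}
    )
    subplots_per_site: int = 4
    terrain: Mapping[str, ZoneTerrain] = field(default_factory=lambda: dict(_DEFAULT_TERRAIN))
    composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {z: dict(w) for z, w in _DEFAULT_COMPOSITION.items()}
    )
    composition_concentration: float = 2.0  # Dirichlet concentration of site mixtures
    trees_per_subplot: int = 10             # multinomial tally behind subplot shares
    volume_sigma: float = 0.55              # lognormal shape; right-skewed
    volume_max: float = 1700.0              # m3/ha, observed ceiling
    subplot_altitude_jitter: float = 5.0    # m
    subplot_slope_jitter: float = 0.5       # degrees
    climate: Mapping[str, SpeciesClimate] = field(default_factory=lambda: dict(_DEFAULT_CLIMATE))
    period_impacts: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_IMPACTS))
    probability_noise_sd: float = 4.0       # percent, shared across periods
    n_empty_sites: int = 0                  # extra all-zero sites, to exercise the drop rule

    def validate(self) -> "GeneratorConfig":
        for zone, n in self.n_sites.items():
            if zone not in self.terrain:
                raise ValueError(f"n_sites: no terrain for zone {zone!r}")
            if zone not in self.composition:
                raise ValueError(f"n_sites: no composition for zone {zone!r}")
            if n < 0:
                raise ValueError(f"n_sites: negative count for zone {zone!r}")
        for zone, t in self.terrain.items():
            if not (0 <= t.rockfall_p <= 1):
                raise ValueError(f"terrain: rockfall_p out of [0, 1] for zone {zone!r}")
        for zone, weights in self.composition.items():
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"composition: negative weight in zone {zone!r}")
            if not weights or sum(weights.values()) <= 0:
                raise ValueError(f"composition: empty mixture for zone {zone!r}")
        if self.subplots_per_site not in (1, 2, 3, 4):
            raise ValueError("subplots_per_site must be 1-4")
        if self.trees_per_subplot < 1:
            raise ValueError("trees_per_subplot must be >= 1")
        for sp, c in self.climate.items():
            if not (0 <= c.decline < 1):
                raise ValueError(f"climate: decline out of [0, 1) for species {sp!r}")
        if self.n_empty_sites < 0:
            raise ValueError("n_empty_sites must be >= 0")
        return self


_ZONE_TAGS = {"alpine_south": "AS", "continental": "CO", "pannonian": "PA", "mediterranean_mountains": "MM"}


def generate_plots(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    registry: SpeciesRegistry | None = None,
) -> tuple[pd.DataFrame, list[PlotRecord], int]:
    """Draw a synthetic subplot table and its centroid aggregation.

    Returns ``(subplots, plots, n_dropped)``: the raw subplot rows, the
    aggregated :class:`PlotRecord` list (one per stocked site, per-zone
    counts equal to the config), and the count of sites dropped because
    no registered species occurred there (the ``n_empty_sites`` extras).
    """
    config = (config or GeneratorConfig()).validate()
    registry = registry or load_registry()
    rng = np.random.default_rng(seed)

    rows = []
    for zone in sorted(config.n_sites):
        terr = config.terrain[zone]
        weights = config.composition[zone]
        codes = sorted(weights)
        unknown = set(codes) - set(registry.codes)
        if unknown:
            raise ValueError(f"composition: unknown species {sorted(unknown)} in zone {zone!r}")
        w = np.array([weights[c] for c in codes], dtype=float)
        w /= w.sum()
        tag = _ZONE_TAGS.get(zone, zone[:2].upper())
        n = config.n_sites[zone]
        for k in range(n):
            site_id = f"{tag}{k + 1:05d}"
            alt = max(0.0, rng.normal(terr.altitude_mean, terr.altitude_sd))
            slope = float(np.clip(rng.normal(terr.slope_mean, terr.slope_sd), 0.0, 89.0))
            lon = rng.uniform(*terr.lon)
            lat = rng.uniform(*terr.lat)
            rockfall = bool(rng.random() < terr.rockfall_p)
            site_mix = rng.dirichlet(w * config.composition_concentration)
            site_volume = float(
                np.clip(
                    rng.lognormal(
                        math.log(terr.volume_mean) - config.volume_sigma**2 / 2.0,
                        config.volume_sigma,
                    ),
                    0.0,
                    config.volume_max,
                )
            )
            for sub in range(config.subplots_per_site):
                counts = rng.multinomial(config.trees_per_subplot, site_mix)
                shares = counts / config.trees_per_subplot
                row = {
                    "site_id": site_id,
                    "subplot": sub + 1,
                    "x": lon + rng.normal(0, 1e-3),
                    "y": lat + rng.normal(0, 1e-3),
                    "zone": zone,
                    "altitude": max(0.0, alt + rng.normal(0, config.subplot_altitude_jitter)),
                    "slope": float(np.clip(slope + rng.normal(0, config.subplot_slope_jitter), 0.0, 89.0)),
                    "volume_m3_ha": float(
                        np.clip(site_volume * rng.lognormal(-0.005, 0.1), 0.0, config.volume_max)
                    ),
                    "rockfall_zone": rockfall,
                }
                for c in registry.codes:
                    row[f"share_{c}"] = 0.0
                for c, s in zip(codes, shares):
                    row[f"share_{c}"] = float(s)
                rows.append(row)
        # optional empty sites exercise the centroid-exclusion rule
    for k in range(config.n_empty_sites):
        zone = sorted(config.n_sites)[0] if config.n_sites else "continental"
        terr = config.terrain.get(zone, _DEFAULT_TERRAIN["continental"])
        site_id = f"XX{k + 1:05d}"
        for sub in range(config.subplots_per_site):
            row = {
                "site_id": site_id,
                "subplot": sub + 1,
                "x": float(np.mean(terr.lon)),
                "y": float(np.mean(terr.lat)),
                "zone": zone,
                "altitude": terr.altitude_mean,
                "slope": terr.slope_mean,
                "volume_m3_ha": 0.0,
                "rockfall_zone": False,
            }
            for c in registry.codes:
                row[f"share_{c}"] = 0.0
            rows.append(row)

    subplots = pd.DataFrame(rows)
    plots, dropped = aggregate_subplots(subplots, registry)
    return subplots, plots, dropped


def generate_suitability(
    plots: Sequence[PlotRecord],
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Occurrence probabilities per plot x species x period (long format).

    The species set is the config's climate models (the two white oaks
    appear as ``qpe``/``qro``; merge them with
    :func:`forest_adapt.suitability.build_suitability_table`).  Additive
    plot-level noise is drawn once per plot and species and shared
    across periods, so a zero-impact period is identical to the
    historical surface.
    """
    config = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(seed)

    altitudes = np.array([p.altitude for p in plots], dtype=float)
    plot_ids = [p.plot_id for p in plots]
    species = sorted(config.climate)
    frames = []
    noise = {
        sp: rng.normal(0.0, config.probability_noise_sd, size=len(plots)) for sp in species
    }
    for sp in species:
        model = config.climate[sp]
        for period, impact in config.period_impacts.items():
            probs = np.clip(model.probability(altitudes, impact) + noise[sp], 0.0, 100.0)
            frames.append(
                pd.DataFrame(
                    {
                        "plot_id": plot_ids,
                        "species": sp,
                        "period": period,
                        "probability": probs,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def expected_avalanche_fraction(config: GeneratorConfig | None = None) -> float:
    """Analytic site-level probability of avalanche eligibility.

    Under the config's normal terrain models, a site is eligible when
    altitude > 800 m and slope lies in [25, 60] degrees; subplot jitter
    is symmetric and small, so the site-level value approximates the
    aggregated-median one.
    """
    config = (config or GeneratorConfig()).validate()
    total = sum(config.n_sites.values())
    if total == 0:
        return 0.0
    acc = 0.0
    for zone, n in config.n_sites.items():
        t = config.terrain[zone]
        p_alt = 1.0 - norm.cdf(800.0, t.altitude_mean, t.altitude_sd)
        p_slope = norm.cdf(60.0, t.slope_mean, t.slope_sd) - norm.cdf(25.0, t.slope_mean, t.slope_sd)
        acc += n * p_alt * p_slope
    return acc / total


def expected_rockfall_fraction(config: GeneratorConfig | None = None) -> float:
    """Expected fraction of sites inside rockfall hazard zones."""
    config = (config or GeneratorConfig()).validate()
    total = sum(config.n_sites.values())
    if total == 0:
        return 0.0
    return sum(n * config.terrain[z].rockfall_p for z, n in config.n_sites.items()) / total


# ---------------------------------------------------------------------------
# Hand-checkable micro-fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("pannonian_spruce", "alpine_protect", "all_fail", "no_change")

_LOW = 5.0    # comfortably below every cut-off
_HIGH = 90.0  # comfortably above every cut-off


def _fixture_table(plot_id: str, future: Mapping[str, float], historical: Mapping[str, float]) -> pd.DataFrame:
    """Raw probability rows for all modelled species over the three periods."""
    species = sorted(set(_DEFAULT_CLIMATE))
    rows = []
    for period in ("historical_1961_1990", "rcp45_2081_2100", "rcp85_2081_2100"):
        source = historical if period == "historical_1961_1990" else future
        for sp in species:
            rows.append((plot_id, sp, period, float(source.get(sp, _LOW))))
    return pd.DataFrame(rows, columns=["plot_id", "species", "period", "probability"])


def scenario_fixture(name: str) -> tuple[list[PlotRecord], pd.DataFrame]:
    """Named micro-fixture: ``(plots, raw suitability table)``.

    * ``pannonian_spruce`` — a pure-spruce lowland plot where only the
      non-native Douglas fir stays suitable: no adaptation and the
      native-pool scenarios leave it unstocked, the combi scenarios
      replant it.
    * ``alpine_protect`` — an avalanche-eligible spruce/larch plot whose
      occurring species all remain suitable: every scenario is the
      identity and the wintergreen share keeps avalanche risk low.
    * ``all_fail`` — nothing is suitable in the future: every scenario
      ends unstocked.
    * ``no_change`` — all occurring species remain suitable: identity.
    """
    if name == "pannonian_spruce":
        plot = PlotRecord("FX_PS", 16.5, 47.8, "pannonian", 250.0, 5.0, {"pab": 1.0}, 300.0, False)
        historical = {sp: _HIGH for sp in _DEFAULT_CLIMATE}
        future = {sp: _LOW for sp in _DEFAULT_CLIMATE}
        future["pme"] = 80.0  # only the NNT Douglas fir stays suitable
        return [plot], _fixture_table(plot.plot_id, future, historical)
    if name == "alpine_protect":
        plot = PlotRecord(
            "FX_AP", 12.0, 47.0, "alpine_south", 1500.0, 35.0, {"pab": 0.7, "lde": 0.3}, 400.0, True
        )
        historical = {sp: _HIGH for sp in _DEFAULT_CLIMATE}
        future = dict(historical)
        return [plot], _fixture_table(plot.plot_id, future, historical)
    if name == "all_fail":
        plot = PlotRecord("FX_AF", 15.0, 48.0, "continental", 600.0, 10.0, {"pab": 0.5, "fsy": 0.5}, 350.0, False)
        historical = {sp: _HIGH for sp in _DEFAULT_CLIMATE}
        future = {sp: _LOW for sp in _DEFAULT_CLIMATE}
        return [plot], _fixture_table(plot.plot_id, future, historical)
    if name == "no_change":
        plot = PlotRecord("FX_NC", 14.0, 47.5, "continental", 800.0, 20.0, {"pab": 0.6, "fsy": 0.4}, 380.0, False)
        historical = {sp: _HIGH for sp in _DEFAULT_CLIMATE}
        future = dict(historical)
        return [plot], _fixture_table(plot.plot_id, future, historical)
    raise ValueError(f"unknown fixture name: {name!r} (expected one of {FIXTURE_NAMES})")
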