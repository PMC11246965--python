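"""Plot-table I/O, subplot aggregation, raster sampling and zone reports.

The analysis unit is the *centroid*: a permanent survey site whose up to
four subplots are aggregated — species shares and stand volume by the
arithmetic mean, altitude and slope by the median.  Sites where none of
the registered species occurs are dropped from the analysis and counted.

Plot tables are delimited text (comma, UTF-8, header row) with one
column per species share, prefixed ``share_``, a ``volume_m3_ha``
column, terrain columns and an environmental-zone column.  Species
suitability can be supplied as long-format tables or sampled from
GeoTIFF probability rasters at the plot coordinates (nearest cell, no
interpolation; coordinates must be in the raster's CRS).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from forest_adapt.registry import SpeciesRegistry, load_registry

logger = logging.getLogger(__name__)

__all__ = [
    "ZONES",
    "PlotRecord",
    "read_plots",
    "write_plots",
    "plots_to_frame",
    "aggregate_subplots",
    "sample_suitability_rasters",
    "zone_summary",
    "write_outputs",
]

ZONES = ("alpine_south", "continental", "pannonian", "mediterranean_mountains")

_SHARE_PREFIX = "share_"
_VOLUME_COL = "volume_m3_ha"


@dataclass
class PlotRecord:
    """One inventory centroid: location, terrain, composition, volume."""

    plot_id: str
    x: float
    y: float
    zone: str
    altitude: float
    slope: float
    shares: dict[str, float] = field(default_factory=dict)
    volume: float = 0.0
    rockfall_zone: bool = False

    def validate(self, registry: SpeciesRegistry | None = None, row: int | None = None) -> "PlotRecord":
        where = f", row {row}" if row is not None else ""
        if self.zone not in ZONES:
            raise ValueError(f"missing or unknown zone {self.zone!r}{where}")
        if self.altitude < 0:
            raise ValueError(f"altitude out of range{where}: {self.altitude}")
        if not (0 <= self.slope < 90):
            raise ValueError(f"slope out of range [0, 90){where}: {self.slope}")
        if self.volume < 0:
            raise ValueError(f"volume out of range{where}: {self.volume}")
        for s, v in self.shares.items():
            if not (0 <= v <= 1):
                raise ValueError(f"share out of range, {s}{where}: {v}")
        if sum(self.shares.values()) > 1 + 1e-9:
            raise ValueError(f"share sum exceeds 1{where}: {sum(self.shares.values()):.4f}")
        if registry is not None:
            unknown = sorted(set(self.shares) - set(registry.codes))
            if unknown:
                raise ValueError(f"unknown species {unknown}{where}")
        return self


def _share_columns(columns: Iterable[str], registry: SpeciesRegistry) -> dict[str, str]:
    """column name -> species code; rejects unregistered species columns."""
    mapping = {}
    for col in columns:
        if col.startswith(_SHARE_PREFIX):
            code = col[len(_SHARE_PREFIX):]
            if code not in registry.codes:
                raise ValueError(f"unknown species column: {col!r}")
            mapping[col] = code
    return mapping


def read_plots(path: str | Path, registry: SpeciesRegistry | None = None) -> list[PlotRecord]:
    """Read a centroid table; row numbers (1-based data rows) are used in errors."""
    registry = registry or load_registry()
    df = pd.read_csv(path)
    required = ["plot_id", "x", "y", "zone", "altitude", "slope", _VOLUME_COL]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"plot table missing columns: {missing}")
    share_cols = _share_columns(df.columns, registry)
    plots = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        shares = {code: float(r[col]) for col, code in share_cols.items() if float(r[col]) > 0}
        plot = PlotRecord(
            plot_id=str(r["plot_id"]),
            x=float(r["x"]),
            y=float(r["y"]),
            zone=str(r["zone"]),
            altitude=float(r["altitude"]),
            slope=float(r["slope"]),
            shares=shares,
            volume=float(r[_VOLUME_COL]),
            rockfall_zone=bool(r.get("rockfall_zone", False)),
        )
        plot.validate(registry, row=i)
        plots.append(plot)
    return plots


def plots_to_frame(plots: Sequence[PlotRecord], registry: SpeciesRegistry | None = None) -> pd.DataFrame:
    registry = registry or load_registry()
    rows = []
    for p in plots:
        row = {
            "plot_id": p.plot_id,
            "x": p.x,
            "y": p.y,
            "zone": p.zone,
            "altitude": p.altitude,
            "slope": p.slope,
            _VOLUME_COL: p.volume,
            "rockfall_zone": p.rockfall_zone,
        }
        for code in registry.codes:
            row[f"{_SHARE_PREFIX}{code}"] = p.shares.get(code, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_plots(plots: Sequence[PlotRecord], path: str | Path, registry: SpeciesRegistry | None = None) -> None:
    plots_to_frame(plots, registry).to_csv(path, index=False)


def aggregate_subplots(
    subplots: pd.DataFrame,
    registry: SpeciesRegistry | None = None,
) -> tuple[list[PlotRecord], int]:
    """Aggregate subplot rows (grouped by ``site_id``) to centroid records.

    Species shares, volume and coordinates aggregate by the arithmetic
    mean; altitude and slope by the median (midpoint of the two central
    values for an even count).  Sites where no registered species occurs
    on any subplot are dropped; the second return value counts them.
    """
    registry = registry or load_registry()
    if "site_id" not in subplots.columns:
        raise ValueError("subplot table missing column 'site_id'")
    share_cols = _share_columns(subplots.columns, registry)
    plots: list[PlotRecord] = []
    dropped = 0
    for site_id, grp in subplots.groupby("site_id", sort=False):
        if len(grp) == 0 or len(grp) > 4:
            raise ValueError(f"site {site_id!r}: expected 1-4 subplots, got {len(grp)}")
        shares = {
            code: float(grp[col].mean()) for col, code in share_cols.items()
        }
        shares = {c: v for c, v in shares.items() if v > 0}
        if not shares:
            dropped += 1
            continue
        zone = grp["zone"].iloc[0]
        plot = PlotRecord(
            plot_id=str(site_id),
            x=float(grp["x"].mean()),
            y=float(grp["y"].mean()),
            zone=str(zone),
            altitude=float(grp["altitude"].median()),
            slope=float(grp["slope"].median()),
            shares=shares,
            volume=float(grp[_VOLUME_COL].mean()),
            rockfall_zone=bool(grp["rockfall_zone"].any()) if "rockfall_zone" in grp.columns else False,
        )
        plot.validate(registry)
        plots.append(plot)
    return plots, dropped


def _read_geotiff(path: str | Path) -> tuple[np.ndarray, tuple[float, float], tuple[float, float]]:
    """Return (array, (origin_x, origin_y), (pixel_sx, pixel_sy)).

    Origin is the top-left corner of the top-left pixel; pixel sizes are
    positive with y decreasing downward (north-up raster).  Requires the
    GeoTIFF ModelPixelScale (33550) and ModelTiepoint (33922) tags.
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tags = page.tags
        try:
            sx, sy, _ = tags[33550].value[:3]
            tie = tags[33922].value[:6]
        except KeyError as exc:
            raise ValueError(f"raster {path}: missing GeoTIFF georeferencing tags") from exc
    i, j, _, ox, oy, _ = tie
    # shift the tiepoint to the top-left corner of pixel (0, 0)
    origin_x = ox - i * sx
    origin_y = oy + j * sy
    return np.asarray(arr, dtype=float), (float(origin_x), float(origin_y)), (float(sx), float(sy))


def sample_suitability_rasters(
    plots: Sequence[PlotRecord],
    rasters: Mapping[tuple[str, str], str | Path],
) -> pd.DataFrame:
    """Nearest-cell occurrence probabilities at plot locations.

    ``rasters`` maps (species code, period) -> GeoTIFF path.  All rasters
    must share the plots' coordinate reference (no reprojection is
    applied).  Values are returned in percent; a raster whose maximum is
    at most 1.5 is auto-detected as a [0, 1] probability surface and
    rescaled by 100 (logged).  Plots outside a raster's extent get a
    missing probability (NaN) and a logged warning.

    Returns a long-format frame (plot_id, species, period, probability).
    """
    rows = []
    for (species, period), path in rasters.items():
        try:
            arr, (ox, oy), (sx, sy) = _read_geotiff(path)
        except Exception as exc:
            raise ValueError(f"unreadable raster for ({species}, {period}): {path} ({exc})") from exc
        scale = 1.0
        finite = arr[np.isfinite(arr)]
        if finite.size and finite.max() <= 1.5:
            scale = 100.0
            logger.info("raster %s detected on [0, 1] scale; rescaling by 100", path)
        nrow, ncol = arr.shape[-2], arr.shape[-1]
        for p in plots:
            col = math.floor((p.x - ox) / sx)
            row = math.floor((oy - p.y) / sy)
            if 0 <= row < nrow and 0 <= col < ncol:
                value = float(arr[row, col]) * scale
                if not np.isfinite(value):
                    value = np.nan
            else:
                value = np.nan
                logger.warning("plot %s outside raster extent of %s", p.plot_id, path)
            rows.append((p.plot_id, species, period, value))
    return pd.DataFrame(rows, columns=["plot_id", "species", "period", "probability"])


def zone_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-zone, per-scenario report: metric means +- SD and category counts.

    ``scores`` is the per-plot score table (see
    :func:`forest_adapt.services.scores_frame`).  Means and sample SDs
    (SD 0 for a single plot) are unweighted over plots; the production
    counts run over all plots of the zone, the avalanche and rockfall
    counts only over the plots eligible for that service.
    """
    rows = []
    for (zone, scenario), grp in scores.groupby(["zone", "scenario"], sort=True):
        row = {"zone": zone, "scenario": scenario, "n_plots": len(grp)}
        for metric in ("richness", "nnt_share", "production_value"):
            row[f"{metric}_mean"] = float(grp[metric].mean())
            sd = float(grp[metric].std(ddof=1)) if len(grp) > 1 else 0.0
            row[f"{metric}_sd"] = sd
        for cat in ("low", "moderate", "high"):
            row[f"production_{cat}"] = int((grp["production_category"] == cat).sum())
        for svc in ("avalanche", "rockfall"):
            eligible = grp.loc[grp[f"{svc}_risk"] != "not_eligible"]
            row[f"{svc}_n"] = len(eligible)
            for cat in ("high", "moderate", "low"):
                row[f"{svc}_{cat}"] = int((eligible[f"{svc}_risk"] == cat).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def _per_plot_wide(scores: pd.DataFrame) -> pd.DataFrame:
    value_cols = [
        c
        for c in scores.columns
        if c not in ("plot_id", "zone", "scenario")
    ]
    wide = scores.pivot(index=["plot_id", "zone"], columns="scenario", values=value_cols)
    wide.columns = [f"{scenario}_{measure}" for measure, scenario in wide.columns]
    return wide.reset_index()


def write_outputs(
    scores: pd.DataFrame,
    out_dir: str | Path,
    plots: Sequence[PlotRecord] | None = None,
    geojson_services: Sequence[str] = ("production", "avalanche", "rockfall"),
) -> dict[str, Path]:
    """Write per-plot and zone-level result tables (and optional GeoJSON).

    Produces ``plot_scores.csv`` (one row per plot, one column per
    scenario x service), ``zone_summary.csv`` (report layout), and — when
    ``plots`` is given for the coordinates — one GeoJSON point layer per
    service whose features carry per-scenario signed ``change``
    attributes in {-1, 0, +1}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    per_plot = out_dir / "plot_scores.csv"
    if scores.empty:
        pd.DataFrame(columns=["plot_id", "zone"]).to_csv(per_plot, index=False)
    else:
        _per_plot_wide(scores).to_csv(per_plot, index=False)
    written["plot_scores"] = per_plot

    zone_path = out_dir / "zone_summary.csv"
    if scores.empty:
        pd.DataFrame(columns=["zone", "scenario", "n_plots"]).to_csv(zone_path, index=False)
    else:
        zone_summary(scores).to_csv(zone_path, index=False)
    written["zone_summary"] = zone_path

    if plots is not None and not scores.empty:
        coords = {p.plot_id: (p.x, p.y) for p in plots}
        scenarios = [s for s in scores["scenario"].unique() if s != "current"]
        for svc in geojson_services:
            change_col = f"change_{svc}"
            if change_col not in scores.columns:
                continue
            features = []
            for plot_id, grp in scores.groupby("plot_id", sort=False):
                if plot_id not in coords:
                    continue
                props = {"plot_id": str(plot_id)}
                for scenario in scenarios:
                    sel = grp.loc[grp["scenario"] == scenario, change_col]
                    if len(sel):
                        props[f"change_{scenario}"] = int(sel.iloc[0])
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {"type": "Point", "coordinates": list(coords[plot_id])},
                        "properties": props,
                    }
                )
            path = out_dir / f"change_{svc}.geojson"
            path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
            written[f"change_{svc}"] = path
    return written
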