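"""Plot I/O, subplot aggregation, raster sampling, zone reports."""

import json

import numpy as np
import pandas as pd
import pytest

from forest_adapt.inventory import (
    PlotRecord,
    aggregate_subplots,
    plots_to_frame,
    read_plots,
    sample_suitability_rasters,
    write_outputs,
    write_plots,
    zone_summary,
)
from forest_adapt.scenarios import run_all
from forest_adapt.services import scores_frame
from forest_adapt.suitability import build_suitability_table
from forest_adapt.synthetic import GeneratorConfig, generate_plots, generate_suitability


def _plot_frame(rows):
    cols = ["plot_id", "x", "y", "zone", "altitude", "slope", "volume_m3_ha", "share_pab", "share_fsy"]
    return pd.DataFrame(rows, columns=cols)


class TestReadPlots:
    def test_valid_file(self, tmp_path, registry):
        path = tmp_path / "plots.csv"
        _plot_frame(
            [
                ("P1", 14.0, 47.5, "continental", 600, 15, 300, 0.6, 0.4),
                ("P2", 14.1, 47.6, "alpine_south", 1400, 30, 450, 1.0, 0.0),
                ("P3", 16.5, 47.9, "pannonian", 250, 3, 200, 0.0, 1.0),
            ]
        ).to_csv(path, index=False)
        plots = read_plots(path, registry)
        assert len(plots) == 3
        assert plots[0].shares == {"pab": 0.6, "fsy": 0.4}
        assert plots[1].shares == {"pab": 1.0}  # zero shares dropped

    def test_share_out_of_range_names_row(self, tmp_path, registry):
        path = tmp_path / "plots.csv"
        _plot_frame(
            [
                ("P1", 14.0, 47.5, "continental", 600, 15, 300, 0.6, 0.4),
                ("P2", 14.1, 47.6, "continental", 600, 15, 300, 1.2, 0.0),
            ]
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match=r"share out of range.*row 2"):
            read_plots(path, registry)

    def test_unknown_species_column(self, tmp_path, registry):
        df = _plot_frame([("P1", 14.0, 47.5, "continental", 600, 15, 300, 0.6, 0.4)])
        df["share_pinus_nigra"] = 0.1
        path = tmp_path / "plots.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="unknown species"):
            read_plots(path, registry)

    def test_missing_zone_rejected(self, tmp_path, registry):
        path = tmp_path / "plots.csv"
        _plot_frame([("P1", 14.0, 47.5, "atlantis", 600, 15, 300, 0.6, 0.4)]).to_csv(path, index=False)
        with pytest.raises(ValueError, match=r"zone.*row 1"):
            read_plots(path, registry)

    def test_roundtrip_preserves_shares_and_volume(self, tmp_path, registry, make_plot):
        plots = [
            make_plot({"pab": 0.123456, "fsy": 0.654321}, volume=321.123456, plot_id="A"),
            make_plot({"pme": 0.5}, volume=0.0, plot_id="B", rockfall_zone=True),
        ]
        path = tmp_path / "plots.csv"
        write_plots(plots, path, registry)
        again = read_plots(path, registry)
        for before, after in zip(plots, again):
            assert after.plot_id == before.plot_id
            assert after.rockfall_zone == before.rockfall_zone
            for code, share in before.shares.items():
                assert after.shares[code] == pytest.approx(share, abs=1e-6)
            assert after.volume == pytest.approx(before.volume, abs=1e-6)


def _subplot_frame(sites):
    """sites: list of (site_id, [(alt, slope, vol, {code: share}), ...])"""
    rows = []
    for site_id, subs in sites:
        for i, (alt, slope, vol, shares) in enumerate(subs):
            row = {
                "site_id": site_id,
                "subplot": i + 1,
                "x": 14.0,
                "y": 47.5,
                "zone": "continental",
                "altitude": alt,
                "slope": slope,
                "volume_m3_ha": vol,
                "share_pab": shares.get("pab", 0.0),
                "share_fsy": shares.get("fsy", 0.0),
            }
            rows.append(row)
    return pd.DataFrame(rows)


class TestAggregateSubplots:
    def test_mean_shares_median_terrain(self, registry):
        subs = _subplot_frame(
            [
                (
                    "S1",
                    [
                        (800, 10, 100, {"pab": 1.0}),
                        (900, 20, 200, {"pab": 0.5}),
                        (1000, 30, 300, {"pab": 0.0}),
                        (1100, 40, 400, {"pab": 0.5}),
                    ],
                )
            ]
        )
        plots, dropped = aggregate_subplots(subs, registry)
        assert dropped == 0
        p = plots[0]
        assert p.shares["pab"] == pytest.approx(0.5)
        assert p.altitude == pytest.approx(950)  # even count: midpoint
        assert p.slope == pytest.approx(25)
        assert p.volume == pytest.approx(250)

    def test_empty_site_dropped_and_counted(self, registry):
        subs = _subplot_frame(
            [
                ("S1", [(800, 10, 100, {"pab": 0.5})] * 4),
                ("S2", [(800, 10, 0, {})] * 4),
            ]
        )
        plots, dropped = aggregate_subplots(subs, registry)
        assert [p.plot_id for p in plots] == ["S1"]
        assert dropped == 1

    def test_permutation_invariance(self, registry):
        subs = _subplot_frame(
            [("S1", [(800, 10, 100, {"pab": 1.0}), (900, 20, 200, {"fsy": 0.6}), (1000, 30, 300, {"pab": 0.2})])]
        )
        shuffled = subs.iloc[[2, 0, 1]].reset_index(drop=True)
        a, _ = aggregate_subplots(subs, registry)
        b, _ = aggregate_subplots(shuffled, registry)
        assert a[0].shares == pytest.approx(b[0].shares)
        assert a[0].altitude == b[0].altitude
        assert a[0].volume == pytest.approx(b[0].volume)

    def test_too_many_subplots_rejected(self, registry):
        subs = _subplot_frame([("S1", [(800, 10, 100, {"pab": 0.5})] * 5)])
        with pytest.raises(ValueError, match="1-4 subplots"):
            aggregate_subplots(subs, registry)


def _write_geotiff(path, data, origin=(10.0, 48.0), pixel=(0.5, 0.5)):
    import tifffile

    sx, sy = pixel
    ox, oy = origin
    tifffile.imwrite(
        path,
        np.asarray(data, dtype="float32"),
        extratags=[
            (33550, "d", 3, (sx, sy, 0.0)),   # ModelPixelScale
            (33922, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),  # ModelTiepoint
        ],
    )


class TestRasterSampling:
    def test_constant_raster_value(self, tmp_path, make_plot):
        path = tmp_path / "p.tif"
        _write_geotiff(path, np.full((4, 4), 73.0))
        # raster covers lon 10-12, lat 46-48 at 0.5 degree cells
        plot = make_plot({"pab": 1.0}, x=10.25, y=47.75, plot_id="P1")
        out = sample_suitability_rasters([plot], {("pab", "rcp85_2081_2100"): path})
        assert out.iloc[0]["probability"] == pytest.approx(73.0)
        assert list(out.columns) == ["plot_id", "species", "period", "probability"]

    def test_nearest_cell_lookup(self, tmp_path, make_plot):
        data = np.arange(16, dtype=float).reshape(4, 4)
        path = tmp_path / "p.tif"
        _write_geotiff(path, data)
        # cell (row 1, col 2): lon 11.0-11.5, lat 47.0-47.5
        plot = make_plot({"pab": 1.0}, x=11.2, y=47.3)
        out = sample_suitability_rasters([plot], {("pab", "rcp45_2081_2100"): path})
        assert out.iloc[0]["probability"] == 6.0

    def test_unit_scale_detected_and_rescaled(self, tmp_path, make_plot):
        path = tmp_path / "p.tif"
        _write_geotiff(path, np.full((4, 4), 0.565))
        plot = make_plot({"pab": 1.0}, x=10.25, y=47.75)
        out = sample_suitability_rasters([plot], {("pab", "rcp85_2081_2100"): path})
        assert out.iloc[0]["probability"] == pytest.approx(56.5)

    def test_outside_extent_is_missing(self, tmp_path, make_plot):
        path = tmp_path / "p.tif"
        _write_geotiff(path, np.full((4, 4), 73.0))
        plot = make_plot({"pab": 1.0}, x=50.0, y=50.0)
        out = sample_suitability_rasters([plot], {("pab", "rcp85_2081_2100"): path})
        assert np.isnan(out.iloc[0]["probability"])

    def test_unreadable_raster_named(self, tmp_path, make_plot):
        path = tmp_path / "nope.tif"
        path.write_text("not a tiff")
        plot = make_plot({"pab": 1.0})
        with pytest.raises(ValueError, match="unreadable raster"):
            sample_suitability_rasters([plot], {("pab", "rcp85_2081_2100"): path})


class TestZoneSummary:
    def _scores(self):
        return pd.DataFrame(
            {
                "plot_id": ["P1", "P2", "P3"],
                "zone": ["continental", "continental", "pannonian"],
                "scenario": ["current"] * 3,
                "richness": [2, 2, 2],
                "nnt_share": [0.0, 0.1, 0.5],
                "production_value": [0.9, 0.9, 0.5],
                "production_category": ["high", "high", "low"],
                "avalanche_risk": ["high", "not_eligible", "not_eligible"],
                "rockfall_risk": ["low", "low", "not_eligible"],
            }
        )

    def test_category_counts_and_moments(self):
        out = zone_summary(self._scores())
        cont = out.loc[out["zone"] == "continental"].iloc[0]
        assert cont["n_plots"] == 2
        assert cont["production_high"] == 2 and cont["production_low"] == 0
        assert cont["richness_mean"] == 2 and cont["richness_sd"] == 0
        assert cont["avalanche_n"] == 1 and cont["avalanche_high"] == 1
        assert cont["rockfall_n"] == 2 and cont["rockfall_low"] == 2
        pann = out.loc[out["zone"] == "pannonian"].iloc[0]
        assert pann["n_plots"] == 1 and pann["production_low"] == 1
        assert pann["nnt_share_sd"] == 0.0  # single plot

    def test_counts_sum_to_eligible_plots(self):
        out = zone_summary(self._scores())
        for _, row in out.iterrows():
            assert row[["production_low", "production_moderate", "production_high"]].sum() == row["n_plots"]
            for svc in ("avalanche", "rockfall"):
                assert row[[f"{svc}_high", f"{svc}_moderate", f"{svc}_low"]].sum() == row[f"{svc}_n"]


class TestWriteOutputs:
    def _small_run(self, registry):
        config = GeneratorConfig(n_sites={"alpine_south": 5, "continental": 5, "pannonian": 3})
        _, plots, _ = generate_plots(config, seed=11, registry=registry)
        raw = generate_suitability(plots, config, seed=12)
        table = build_suitability_table(raw, registry)
        results = run_all(plots, table, "rcp85_2081_2100", registry)
        scores = scores_frame(plots, results, registry)
        return plots, scores

    def test_files_written(self, tmp_path, registry):
        plots, scores = self._small_run(registry)
        written = write_outputs(scores, tmp_path, plots=plots)
        per_plot = pd.read_csv(written["plot_scores"])
        assert len(per_plot) == len(plots)
        zones = pd.read_csv(written["zone_summary"])
        assert set(zones["zone"]) <= {"alpine_south", "continental", "pannonian"}
        # one column per scenario x service in the wide table
        assert any(c.startswith("no_adaptation_") for c in per_plot.columns)

    def test_geojson_change_attributes(self, tmp_path, registry):
        plots, scores = self._small_run(registry)
        written = write_outputs(scores, tmp_path, plots=plots)
        layer = json.loads(written["change_production"].read_text())
        assert layer["type"] == "FeatureCollection"
        assert len(layer["features"]) == len(plots)
        for feat in layer["features"]:
            for key, val in feat["properties"].items():
                if key.startswith("change_"):
                    assert val in (-1, 0, 1)

    def test_empty_scores(self, tmp_path):
        written = write_outputs(pd.DataFrame(), tmp_path)
        assert written["plot_scores"].exists()
        assert written["zone_summary"].exists()


def test_plot_record_validation(make_plot, registry):
    with pytest.raises(ValueError, match="slope"):
        make_plot({"pab": 1.0}, slope=95.0).validate(registry)
    with pytest.raises(ValueError, match="share sum"):
        make_plot({"pab": 0.8, "fsy": 0.4}).validate(registry)
    with pytest.raises(ValueError, match="unknown species"):
        make_plot({"xxx": 0.5}).validate(registry)
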