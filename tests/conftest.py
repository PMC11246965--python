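import pytest

from forest_adapt.inventory import PlotRecord
from forest_adapt.registry import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def make_plot():
    """Factory for plot records with sensible defaults."""

    def _make(
        shares,
        volume=300.0,
        plot_id="P1",
        zone="continental",
        altitude=600.0,
        slope=15.0,
        rockfall_zone=False,
        x=14.0,
        y=47.5,
    ):
        return PlotRecord(plot_id, x, y, zone, altitude, slope, dict(shares), volume, rockfall_zone)

    return _make
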