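import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reefcast.climate_forcing import ClimateSeries
from reefcast.community import ParrotfishRecord, TransectState

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    # states are frozen dataclasses, so sharing a fixture across examples is safe
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_series(sst_by_month, start_year=2019, omega=3.9, label="test"):
    """Build a ClimateSeries from a flat list of monthly SSTs (complete years)."""
    sst = np.asarray(sst_by_month, dtype=float)
    n_years = len(sst) // 12
    years = np.repeat(np.arange(start_year, start_year + n_years), 12)
    months = np.tile(np.arange(1, 13), n_years)
    return ClimateSeries(
        scenario_label=label,
        years=years,
        months=months,
        sst=sst,
        omega_ar=np.full(len(sst), omega),
    )


@pytest.fixture
def flat_series():
    """Three cool years at a constant 28 °C."""
    return make_series([28.0] * 36)


@pytest.fixture
def simple_state():
    """Single-taxon transect with all census components populated."""
    return TransectState(
        transect_id="T1",
        coral_cover={"Orbicella faveolata": 25.0},
        cca_cover=4.0,
        sand_cover=20.0,
        substrate_cover=30.0,
        rugosity=1.5,
        sponge_cover={"Cliona varians": 200.0},
        urchin_sizes={"Echinometra": (3.0, 4.0)},
        parrotfish_census=(ParrotfishRecord("Sparisoma viride", "initial", "15-24", 2),),
    )
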