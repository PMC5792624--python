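import numpy as np
import pytest

import roadrisk as rr


@pytest.fixture(scope="session")
def small_study():
    """20-unit synthetic study with default planted coefficients."""
    return rr.gen_study(n_units=20, seed=42)


@pytest.fixture(scope="session")
def punjab():
    """Unit carrying the published Punjab 2010–2012 death counts."""
    return rr.AreaUnit(
        unit_id="PB",
        name="Punjab",
        is_island=False,
        population=27_743_338,
        urban_population=10_399_146,
        built_up_area_km2=2500.0,
        nh_length_km=1739.0,
        diesel_kt=2860.0,
        deaths_by_year={2010: 2133, 2011: 4897, 2012: 4795},
    )


@pytest.fixture()
def toy_bins():
    """Hand-sized commute-bin table with every mode populated."""
    counts = np.zeros((len(rr.MODES), len(rr.BINS)))
    counts[rr.MODES.index("walk"), 0] = 1000  # 0-1 km
    counts[rr.MODES.index("walk"), 1] = 500
    counts[rr.MODES.index("cycle"), 1] = 800
    counts[rr.MODES.index("cycle"), 3] = 100
    counts[rr.MODES.index("2W"), 2] = 600
    counts[rr.MODES.index("car"), 3] = 200
    counts[rr.MODES.index("IPT"), 1] = 300
    counts[rr.MODES.index("bus"), 0] = 50
    counts[rr.MODES.index("bus"), 3] = 400
    counts[rr.MODES.index("train"), 5] = 250
    return rr.CommuteBinTable(unit_id="T1", counts=counts)
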