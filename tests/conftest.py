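import datetime as dt

import numpy as np
import pandas as pd
import pytest

from mastmix.study_data import NightRecord, Site, Study, TrapSession


@pytest.fixture
def tiny_site() -> Site:
    return Site(
        site_id="PFb",
        landform="basin",
        n_stations=25,
        station_spacing_m=15.0,
        area_ha=0.5625,
        first_year=2004,
        last_year=2019,
    )


@pytest.fixture
def tiny_study(tiny_site) -> Study:
    """Smallest valid study: one site, one session, two nights."""
    session = TrapSession(
        session_id=1,
        site_id="PFb",
        start_date=dt.date(2010, 6, 15),
        n_nights=2,
        counts={"myodes": np.array([3, 1])},
    )
    nights = [
        NightRecord(1, 1, 9.5, 0.0),
        NightRecord(1, 2, 11.0, 4.2),
    ]
    seeds = pd.DataFrame(
        dict(
            landform=["basin"] * 6,
            trap_id=[1, 2, 3, 1, 2, 3],
            period=[2009] * 6,
            species=["fagus"] * 3 + ["picea"] * 3,
            seeds=[12, 0, 30, 4, 4, 1],
        )
    )
    return Study(
        sites={"PFb": tiny_site},
        sessions=[session],
        night_records=nights,
        seed_counts=seeds,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20210813)
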