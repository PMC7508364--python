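import pandas as pd
import pytest

from bedmix import ActivityTable, aggregate
from bedmix.datasets import (
    load_hospital_activity,
    load_icu_activity,
    load_reported_casemix,
)


@pytest.fixture(scope="session")
def hospital_activity() -> ActivityTable:
    """All-ward regional activity, 2010 & 2017 (21 regions x 2 years)."""
    return load_hospital_activity()


@pytest.fixture(scope="session")
def icu_activity() -> ActivityTable:
    """Intensive-care regional activity, 2010 & 2017."""
    return load_icu_activity()


@pytest.fixture(scope="session")
def reported_casemix() -> pd.DataFrame:
    """Published 2017 all-ward CMI/PI per region."""
    return load_reported_casemix("all")


@pytest.fixture(scope="session")
def national_2017(hospital_activity) -> pd.Series:
    """National all-ward 2017 totals (one aggregate row)."""
    return aggregate(hospital_activity.subset(year=2017), by=["ward", "year"]).df.iloc[0]


def make_table(rows, provenance="test") -> ActivityTable:
    """Rows of (region, ward, year, beds, discharges, inpatient_days)."""
    return ActivityTable(
        pd.DataFrame(
            rows,
            columns=["region", "ward", "year", "beds", "discharges", "inpatient_days"],
        ),
        provenance,
    )


@pytest.fixture()
def two_ward_table() -> ActivityTable:
    """Two regions over wards A-like (short stay) and B-like (long stay).

    Nationally: cardiology d=200 days=1000 (AvLOS 5), long_term_care d=200
    days=3000 (AvLOS 15); shares 0.5/0.5, overall AvLOS 10.
    """
    return make_table(
        [
            ("north", "cardiology", 2017, 10, 150, 750),
            ("north", "long_term_care", 2017, 10, 50, 750),
            ("south", "cardiology", 2017, 10, 50, 250),
            ("south", "long_term_care", 2017, 30, 150, 2250),
        ]
    )
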