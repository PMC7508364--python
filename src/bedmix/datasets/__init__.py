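"""Packaged reference datasets.

Small transcriptions of the Italian Ministry of Health annual hospital
activity publication (public and private institutes, private nursing homes
excluded) for the years 2010 and 2017, and the published 2017 regional
case-mix / performance indices computed against the national benchmark.
Loaders return validated :class:`~bedmix.data.ActivityTable` objects or
plain DataFrames.
"""

from importlib import resources

import pandas as pd

from ..data import ActivityTable, read_activity_csv

__all__ = [
    "load_hospital_activity",
    "load_icu_activity",
    "load_reported_casemix",
]


def _path(name: str):
    return resources.files(__package__) / name


def load_hospital_activity() -> ActivityTable:
    """All-ward regional activity (beds, discharges, inpatient days), 2010 & 2017.

    21 regions/autonomous provinces x 2 years, ward code ``"all"``.
    """
    with resources.as_file(_path("table1_2010_2017.csv")) as p:
        return read_activity_csv(
            p, provenance="Ministry of Health annual publication, all wards, 2010/2017"
        )


def load_icu_activity() -> ActivityTable:
    """Intensive-care-unit regional activity, 2010 & 2017."""
    with resources.as_file(_path("table2_icu_2010_2017.csv")) as p:
        return read_activity_csv(
            p, provenance="Ministry of Health annual publication, ICU ward, 2010/2017"
        )


def load_reported_casemix(ward: str = "all") -> pd.DataFrame:
    """Published 2017 regional CMI/PI against the national benchmark.

    Parameters
    ----------
    ward : ``"all"`` or ``"intensive_care"``.

    Returns a DataFrame ``region, ward, year, cmi, pi`` (21 rows).  These
    indices are not recomputable from the regional aggregates above — they
    need per-ward per-region discharge data — so the published values are
    shipped for the quadrant analysis.
    """
    name = {"all": "casemix_2017.csv", "intensive_care": "casemix_icu_2017.csv"}
    if ward not in name:
        raise ValueError(f"ward must be one of {sorted(name)}, got {ward!r}")
    with resources.as_file(_path(name[ward])) as p:
        return pd.read_csv(p)
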