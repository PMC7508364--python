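"""Hospital bed-management indicators.

Four classical indicators computed from annual (region, ward) aggregates:

- **BOR**, bed occupancy rate: percent of the bed-day endowment actually
  occupied, ``100 * inpatient_days / (beds * period_days)``;
- **AvLOS**, average length of stay: ``inpatient_days / discharges`` (days);
- **TOI**, turnover interval: mean empty-bed days between a discharge and
  the next admission, ``(beds * period_days - inpatient_days) / discharges``;
- **BTO**, bed turnover: patients treated per bed per period,
  ``discharges / beds``.

The identities ``TOI = period_days/BTO - AvLOS`` and
``AvLOS = (BOR/100) * period_days / BTO`` hold for every row and are used
as internal consistency checks.  Occupancy above the endowment (BOR > 100,
negative TOI) is representable and flagged — never clamped — because surge
analysis needs it.

``period_days`` defaults to 365, the accounting year of the national
publication; pass 366 for leap years.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import ActivityTable, aggregate
from .errors import IndicatorOverflowWarning, UndefinedIndicatorError
from .rounding import round_half_up

__all__ = [
    "compute_avlos",
    "compute_bor",
    "compute_toi",
    "compute_bto",
    "compute_indicator_table",
    "format_indicator_table",
    "percent_difference",
    "compute_deltas",
    "beds_per_100k",
    "surge_occupancy",
    "surge_table",
]

PERIOD_DAYS = 365


def compute_avlos(inpatient_days: float, discharges: float) -> float:
    """Average length of stay in days; undefined without discharges."""
    if discharges <= 0:
        raise UndefinedIndicatorError("AvLOS undefined: no discharges")
    return inpatient_days / discharges


def compute_bor(
    inpatient_days: float, beds: float, period_days: int = PERIOD_DAYS
) -> float:
    """Bed occupancy rate in percent of the bed-day endowment."""
    if beds <= 0:
        raise UndefinedIndicatorError("BOR undefined: no beds")
    if period_days <= 0:
        raise UndefinedIndicatorError("BOR undefined: non-positive period")
    bor = 100.0 * inpatient_days / (beds * period_days)
    if bor > 100.0:
        warnings.warn(
            f"BOR {bor:.1f}% exceeds the bed endowment",
            IndicatorOverflowWarning,
            stacklevel=2,
        )
    return bor


def compute_toi(
    beds: float,
    inpatient_days: float,
    discharges: float,
    period_days: int = PERIOD_DAYS,
) -> float:
    """Turnover interval: empty-bed days per discharge."""
    if discharges <= 0:
        raise UndefinedIndicatorError("TOI undefined: no discharges")
    toi = (beds * period_days - inpatient_days) / discharges
    if toi < 0:
        warnings.warn(
            f"negative TOI {toi:.2f}: occupancy above the bed endowment",
            IndicatorOverflowWarning,
            stacklevel=2,
        )
    return toi


def compute_bto(discharges: float, beds: float) -> float:
    """Bed turnover: discharges per available bed per period."""
    if beds <= 0:
        raise UndefinedIndicatorError("BTO undefined: no beds")
    return discharges / beds


def compute_indicator_table(
    table: ActivityTable,
    period_days: int = PERIOD_DAYS,
    *,
    include_total: bool = True,
    total_label: str = "Total",
) -> pd.DataFrame:
    """Indicators for every (region, ward, year) row, plus aggregate rows.

    Returns a DataFrame ``region, ward, year, beds, discharges,
    inpatient_days, toi, bor, avlos, bto, period_days, flags``.  Rows with a
    zero denominator get NaN for the affected indicators and an explanatory
    flag instead of aborting the table; occupancy above the endowment is
    flagged ``bor_overflow`` / ``negative_toi``.  With ``include_total`` a
    summed row per (ward, year) is appended under ``total_label``.
    """
    frames = [table.df.copy()]
    if include_total:
        totals = aggregate(table, by=["ward", "year"]).df.copy()
        totals["region"] = total_label
        frames.append(totals)
    df = pd.concat(frames, ignore_index=True)

    beds = df["beds"].to_numpy(float)
    disch = df["discharges"].to_numpy(float)
    days = df["inpatient_days"].to_numpy(float)
    endow = beds * float(period_days)

    with np.errstate(divide="ignore", invalid="ignore"):
        bor = np.where(beds > 0, 100.0 * days / endow, np.nan)
        avlos = np.where(disch > 0, days / disch, np.nan)
        toi = np.where(disch > 0, (endow - days) / disch, np.nan)
        bto = np.where(beds > 0, disch / beds, np.nan)

    flags = []
    for i in range(len(df)):
        f = []
        if beds[i] <= 0:
            f.append("undefined_bor_bto")
        if disch[i] <= 0:
            f.append("undefined_avlos_toi")
        if beds[i] > 0 and bor[i] > 100.0:
            f.append("bor_overflow")
        if disch[i] > 0 and toi[i] < 0:
            f.append("negative_toi")
        flags.append(";".join(f))

    out = df.copy()
    out["toi"] = toi
    out["bor"] = bor
    out["avlos"] = avlos
    out["bto"] = bto
    out["period_days"] = int(period_days)
    out["flags"] = flags
    return out


def format_indicator_table(ind: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: BOR to integer percent, the rest to 2 decimals."""
    out = ind.copy()
    out["bor"] = out["bor"].map(
        lambda x: round_half_up(x, 0) if pd.notna(x) else np.nan
    )
    for col in ("toi", "avlos", "bto"):
        out[col] = out[col].map(
            lambda x: round_half_up(x, 2) if pd.notna(x) else np.nan
        )
    return out


def percent_difference(value_from: float, value_to: float) -> float:
    """Relative change in percent, ``100 * (to - from) / from``."""
    if value_from == 0:
        raise UndefinedIndicatorError("percent difference undefined from 0")
    return 100.0 * (value_to - value_from) / value_from


def compute_deltas(
    table: ActivityTable, year_from: int, year_to: int
) -> pd.DataFrame:
    """Inter-year percent differences per (region, ward) and quantity.

    Returns ``region, ward, quantity, value_from, value_to,
    percent_difference`` in long form, one row per quantity in
    {beds, discharges, inpatient_days}.  Units absent in either year, or
    with a zero baseline, get NaN and appear with a flag column set.
    """
    a = table.subset(year=year_from).df.set_index(["region", "ward"])
    b = table.subset(year=year_to).df.set_index(["region", "ward"])
    keys = a.index.intersection(b.index)
    rows = []
    for region, ward in keys:
        for qty in ("beds", "discharges", "inpatient_days"):
            v0 = float(a.loc[(region, ward), qty])
            v1 = float(b.loc[(region, ward), qty])
            if v0 == 0:
                pct, flag = np.nan, "undefined_delta"
            else:
                pct, flag = percent_difference(v0, v1), ""
            rows.append((region, ward, qty, v0, v1, pct, flag))
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "ward",
            "quantity",
            "value_from",
            "value_to",
            "percent_difference",
            "flags",
        ],
    )


def beds_per_100k(beds: float, population: float) -> float:
    """Bed endowment per 100,000 inhabitants."""
    if population <= 0:
        raise UndefinedIndicatorError("population must be positive")
    return 100_000.0 * beds / population


def surge_occupancy(icu_covid_patients: float, reference_beds: float) -> float:
    """Pandemic ICU census as percent of a reference-year bed endowment.

    Values above 100 are meaningful (routine capacity exceeded) and are the
    caller's cue that the region is saturated; nothing is clipped.
    """
    if reference_beds <= 0:
        raise UndefinedIndicatorError("surge occupancy undefined: no reference beds")
    return 100.0 * icu_covid_patients / reference_beds


def surge_table(
    census: pd.DataFrame, reference: ActivityTable, beds_year: int
) -> pd.DataFrame:
    """Per-region surge occupancy of a daily ICU census against a bed baseline.

    ``census`` has columns ``region, date, icu_covid_patients``; the bed
    baseline is the ICU endowment of ``beds_year`` in ``reference``.
    Returns one row per (region, date) with ``occupancy_pct`` and a
    ``saturated`` flag at >= 100%.
    """
    beds = (
        reference.subset(year=beds_year)
        .df.set_index("region")["beds"]
        .to_dict()
    )
    rows = []
    for row in census.itertuples(index=False):
        if row.region not in beds:
            continue
        pct = surge_occupancy(row.icu_covid_patients, beds[row.region])
        rows.append((row.region, row.date, row.icu_covid_patients, pct, pct >= 100.0))
    return pd.DataFrame(
        rows,
        columns=["region", "date", "icu_covid_patients", "occupancy_pct", "saturated"],
    )
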