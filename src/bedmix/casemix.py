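"""Case-Mix and Performance indices by indirect standardisation of LOS.

Both indices compare a unit (a region's hospital system) with a reference
population (the national aggregate) through the ward composition of its
discharges, writing ``AvLOS_j`` for the mean length of stay in ward *j* and
``d_j`` for discharges there:

    CMI = [ sum_j AvLOS_j^REF * (d_j^STR / d_ALL^STR) ] / AvLOS_ALL^REF
    PI  = [ sum_j AvLOS_j^STR * (d_j^REF / d_ALL^REF) ] / AvLOS_ALL^REF

CMI values the unit's own discharge mix at the reference ward-specific
AvLOS: above 1 means the unit admits into long-stay (complex) wards more
than the reference does.  PI values the unit's own ward AvLOS at the
reference mix: above 1 means longer stays than the standard at equal
complexity, i.e. lower efficiency.  The denominator is the reference
overall AvLOS by default; ``denominator="regional"`` divides by the unit's
own overall AvLOS instead (a variant found in some worked presentations of
these indices — see docs/methods.md).

Wards present in only one of unit/reference are excluded and the weights
renormalised over the shared set; ``coverage`` reports the share of the
unit's discharges that the shared set retains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .data import ActivityTable, aggregate
from .errors import BenchmarkError, UndefinedIndicatorError

__all__ = [
    "Benchmark",
    "RegionalProfile",
    "CaseMixResult",
    "build_benchmark",
    "profile_region",
    "compute_cmi",
    "compute_pi",
    "compute_casemix",
    "casemix_table",
    "ward_day_share",
]

_TOL = 1e-9


@dataclass(frozen=True)
class Benchmark:
    """Reference population: per-ward AvLOS, discharge shares, overall AvLOS."""

    year: int
    avlos_by_ward: Mapping[str, float]
    discharge_share_by_ward: Mapping[str, float]
    avlos_all: float
    d_all: int

    def __post_init__(self) -> None:
        shares = self.discharge_share_by_ward
        if abs(sum(shares.values()) - 1.0) > _TOL:
            raise BenchmarkError("discharge shares must sum to 1")
        mean = sum(self.avlos_by_ward[w] * s for w, s in shares.items())
        if abs(mean - self.avlos_all) > max(_TOL, _TOL * abs(self.avlos_all)):
            raise BenchmarkError(
                "overall AvLOS is not the share-weighted ward mean; "
                "build the benchmark from one consistent table"
            )

    @property
    def wards(self) -> tuple[str, ...]:
        return tuple(self.avlos_by_ward)


@dataclass(frozen=True)
class RegionalProfile:
    """One region's per-ward discharge counts and AvLOS for a year."""

    region: str
    year: int
    discharges_by_ward: Mapping[str, int]
    avlos_by_ward: Mapping[str, float]  # only wards with discharges > 0
    d_all: int
    avlos_all: float


@dataclass(frozen=True)
class CaseMixResult:
    region: str
    year: int
    cmi: float
    pi: float
    wards_used: int
    coverage: float


def build_benchmark(reference: ActivityTable, year: int | None = None) -> Benchmark:
    """Build the reference from a one-year per-ward activity table.

    The table must hold ward-level rows only (an ``"all"`` row mixed with
    ward rows would double-count).  Several regions may be present; they are
    aggregated per ward first, so passing the whole country's per-ward table
    yields the national benchmark.
    """
    df = reference.df
    if year is not None:
        df = df[df["year"] == year]
        if len(df) == 0:
            raise BenchmarkError(f"no reference rows for year {year}")
    years = df["year"].unique()
    if len(years) > 1:
        raise BenchmarkError(
            f"reference spans years {sorted(map(int, years))}; pass year="
        )
    wards = set(df["ward"])
    if "all" in wards and len(wards) > 1:
        raise BenchmarkError("'all' rows mixed with ward rows in the reference")
    per_ward = aggregate(ActivityTable(df.copy()), by=["ward", "year"]).df
    bad = per_ward[(per_ward["discharges"] == 0) & (per_ward["inpatient_days"] > 0)]
    if len(bad):
        raise BenchmarkError(
            f"ward(s) with inpatient days but no discharges: {sorted(bad['ward'])}"
        )
    per_ward = per_ward[per_ward["discharges"] > 0]
    if len(per_ward) == 0:
        raise BenchmarkError("no reference ward has any discharges")
    d_all = int(per_ward["discharges"].sum())
    avlos = {
        r.ward: r.inpatient_days / r.discharges for r in per_ward.itertuples()
    }
    shares = {r.ward: r.discharges / d_all for r in per_ward.itertuples()}
    avlos_all = float(per_ward["inpatient_days"].sum()) / d_all
    return Benchmark(
        year=int(years[0]),
        avlos_by_ward=avlos,
        discharge_share_by_ward=shares,
        avlos_all=avlos_all,
        d_all=d_all,
    )


def profile_region(table: ActivityTable, region: str, year: int) -> RegionalProfile:
    """Per-ward discharge counts and AvLOS for one region and year."""
    df = table.df
    df = df[(df["region"] == region) & (df["year"] == year)]
    if len(df) == 0:
        raise BenchmarkError(f"region {region!r} has no rows for {year}")
    wards = set(df["ward"])
    if "all" in wards and len(wards) > 1:
        raise BenchmarkError("'all' rows mixed with ward rows for the region")
    discharges = {r.ward: int(r.discharges) for r in df.itertuples()}
    avlos = {
        r.ward: r.inpatient_days / r.discharges
        for r in df.itertuples()
        if r.discharges > 0
    }
    d_all = int(df["discharges"].sum())
    if d_all == 0:
        raise UndefinedIndicatorError(f"region {region!r} has no discharges in {year}")
    avlos_all = float(df["inpatient_days"].sum()) / d_all
    return RegionalProfile(
        region=region,
        year=year,
        discharges_by_ward=discharges,
        avlos_by_ward=avlos,
        d_all=d_all,
        avlos_all=avlos_all,
    )


def _shared_wards(profile: RegionalProfile, benchmark: Benchmark) -> list[str]:
    shared = [
        w
        for w in benchmark.avlos_by_ward
        if profile.discharges_by_ward.get(w, 0) > 0
    ]
    if not shared:
        raise BenchmarkError(
            f"region {profile.region!r} shares no active ward with the benchmark"
        )
    return shared


def _denominator(
    profile: RegionalProfile, benchmark: Benchmark, denominator: str
) -> float:
    if denominator == "national":
        value = benchmark.avlos_all
    elif denominator == "regional":
        value = profile.avlos_all
    else:
        raise ValueError("denominator must be 'national' or 'regional'")
    if value == 0:
        raise BenchmarkError("overall AvLOS of the denominator population is 0")
    return value


def compute_cmi(
    profile: RegionalProfile,
    benchmark: Benchmark,
    denominator: str = "national",
) -> float:
    """Case-Mix Index: reference ward AvLOS weighted by the unit's mix."""
    shared = _shared_wards(profile, benchmark)
    d_shared = sum(profile.discharges_by_ward[w] for w in shared)
    num = sum(
        benchmark.avlos_by_ward[w] * profile.discharges_by_ward[w] / d_shared
        for w in shared
    )
    return num / _denominator(profile, benchmark, denominator)


def compute_pi(
    profile: RegionalProfile,
    benchmark: Benchmark,
    denominator: str = "national",
) -> float:
    """Performance Index: the unit's ward AvLOS weighted by the reference mix."""
    shared = _shared_wards(profile, benchmark)
    s_shared = sum(benchmark.discharge_share_by_ward[w] for w in shared)
    num = sum(
        profile.avlos_by_ward[w] * benchmark.discharge_share_by_ward[w] / s_shared
        for w in shared
    )
    return num / _denominator(profile, benchmark, denominator)


def compute_casemix(
    profile: RegionalProfile,
    benchmark: Benchmark,
    denominator: str = "national",
    *,
    allow_cross_year: bool = False,
) -> CaseMixResult:
    """CMI and PI for one region against a benchmark, with coverage."""
    if profile.year != benchmark.year and not allow_cross_year:
        raise BenchmarkError(
            f"profile year {profile.year} != benchmark year {benchmark.year}; "
            "pass allow_cross_year=True to standardise across years"
        )
    shared = _shared_wards(profile, benchmark)
    coverage = (
        sum(profile.discharges_by_ward[w] for w in shared) / profile.d_all
        if profile.d_all
        else 0.0
    )
    if coverage < 1.0 - _TOL:
        warnings.warn(
            f"region {profile.region!r}: only {coverage:.1%} of discharges fall "
            "in wards shared with the benchmark",
            stacklevel=2,
        )
    return CaseMixResult(
        region=profile.region,
        year=profile.year,
        cmi=compute_cmi(profile, benchmark, denominator),
        pi=compute_pi(profile, benchmark, denominator),
        wards_used=len(shared),
        coverage=coverage,
    )


def casemix_table(
    table: ActivityTable,
    year: int,
    benchmark: Benchmark | None = None,
    denominator: str = "national",
) -> pd.DataFrame:
    """CMI/PI for every region in a per-ward activity table.

    When ``benchmark`` is omitted it is built from the aggregate of the
    table itself (the national benchmark of the year under analysis).
    Returns ``region, year, cmi, pi, wards_used, coverage``.
    """
    sub = table.subset(year=year)
    if benchmark is None:
        benchmark = build_benchmark(sub, year=year)
    rows = []
    for region in sub.df["region"].unique():
        res = compute_casemix(
            profile_region(sub, region, year), benchmark, denominator
        )
        rows.append(
            (res.region, res.year, res.cmi, res.pi, res.wards_used, res.coverage)
        )
    return pd.DataFrame(
        rows, columns=["region", "year", "cmi", "pi", "wards_used", "coverage"]
    )


def ward_day_share(reference: ActivityTable, ward: str) -> float:
    """Share of reference inpatient days spent in one ward.

    The denominator is the explicit ``"all"`` row when present (so an
    all-ward table and a single-ward table can be combined), otherwise the
    sum over the ward rows.
    """
    df = reference.df
    ward_rows = df[df["ward"] == ward]
    if len(ward_rows) == 0:
        raise BenchmarkError(f"ward {ward!r} absent from the reference table")
    all_rows = df[df["ward"] == "all"]
    if ward == "all" or len(all_rows) == 0:
        total = float(df["inpatient_days"].sum())
    else:
        total = float(all_rows["inpatient_days"].sum())
    if total <= 0:
        raise UndefinedIndicatorError("reference total inpatient days is 0")
    return float(ward_rows["inpatient_days"].sum()) / total
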