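"""Benchmark construction and CMI/PI standardisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bedmix import (
    Benchmark,
    aggregate,
    build_benchmark,
    casemix_table,
    compute_casemix,
    compute_cmi,
    compute_pi,
    profile_region,
    ward_day_share,
)
from bedmix.casemix import RegionalProfile
from bedmix.data import ActivityTable
from bedmix.errors import BenchmarkError

from conftest import make_table


def toy_benchmark() -> Benchmark:
    """Two wards: AvLOS {A:5, B:15}, shares 0.5/0.5, overall 10."""
    return build_benchmark(
        make_table(
            [
                ("all", "cardiology", 2017, 10, 100, 500),
                ("all", "long_term_care", 2017, 10, 100, 1500),
            ]
        )
    )


def profile(region, year, discharges, avlos):
    d_all = sum(discharges.values())
    days = sum(d * avlos[w] for w, d in discharges.items() if d > 0)
    return RegionalProfile(
        region=region,
        year=year,
        discharges_by_ward=discharges,
        avlos_by_ward=avlos,
        d_all=d_all,
        avlos_all=days / d_all,
    )


class TestBuildBenchmark:
    def test_two_ward_toy(self):
        b = toy_benchmark()
        assert b.avlos_by_ward == {"cardiology": 5.0, "long_term_care": 15.0}
        assert b.discharge_share_by_ward == {
            "cardiology": 0.5,
            "long_term_care": 0.5,
        }
        assert b.avlos_all == 10.0
        assert b.d_all == 200

    def test_single_ward(self):
        b = build_benchmark(make_table([("all", "cardiology", 2017, 10, 100, 600)]))
        assert b.discharge_share_by_ward == {"cardiology": 1.0}
        assert b.avlos_all == b.avlos_by_ward["cardiology"] == 6.0

    def test_national_all_ward_overall_avlos(self, hospital_activity):
        """The 2017 national overall AvLOS is 7.95 days."""
        b = build_benchmark(hospital_activity, year=2017)
        assert round(b.avlos_all, 2) == 7.95

    def test_days_without_discharges_rejected(self):
        with pytest.raises(BenchmarkError):
            build_benchmark(make_table([("all", "cardiology", 2017, 10, 0, 100)]))

    def test_all_rows_mixed_with_ward_rows_rejected(self):
        with pytest.raises(BenchmarkError):
            build_benchmark(
                make_table(
                    [
                        ("x", "all", 2017, 10, 100, 500),
                        ("x", "cardiology", 2017, 10, 100, 500),
                    ]
                )
            )

    def test_multi_year_needs_explicit_year(self, icu_activity):
        with pytest.raises(BenchmarkError):
            build_benchmark(icu_activity)
        assert build_benchmark(icu_activity, year=2017).year == 2017


class TestProfileRegion:
    def test_toy_region(self, two_ward_table):
        p = profile_region(two_ward_table, "north", 2017)
        assert p.discharges_by_ward == {"cardiology": 150, "long_term_care": 50}
        assert p.avlos_all == 7.5
        assert p.avlos_by_ward == {"cardiology": 5.0, "long_term_care": 15.0}

    def test_zero_discharge_ward_kept_in_counts_only(self):
        table = make_table(
            [
                ("r", "cardiology", 2017, 10, 100, 500),
                ("r", "oncology", 2017, 5, 0, 0),
            ]
        )
        p = profile_region(table, "r", 2017)
        assert "oncology" in p.discharges_by_ward
        assert "oncology" not in p.avlos_by_ward

    def test_absent_region_raises(self, two_ward_table):
        with pytest.raises(BenchmarkError):
            profile_region(two_ward_table, "centre", 2017)


class TestIndices:
    def test_cmi_toy_mix(self, two_ward_table):
        b = build_benchmark(two_ward_table)
        north = profile_region(two_ward_table, "north", 2017)
        south = profile_region(two_ward_table, "south", 2017)
        # (5*0.75 + 15*0.25)/10 and (5*0.25 + 15*0.75)/10
        assert compute_cmi(north, b) == pytest.approx(0.75)
        assert compute_cmi(south, b) == pytest.approx(1.25)

    def test_cmi_one_when_mix_matches_benchmark(self):
        b = toy_benchmark()
        p = profile(
            "r", 2017, {"cardiology": 70, "long_term_care": 70},
            {"cardiology": 4.0, "long_term_care": 12.0},
        )
        assert compute_cmi(p, b) == pytest.approx(1.0)

    def test_cmi_one_for_single_shared_ward(self):
        b = build_benchmark(make_table([("all", "cardiology", 2017, 10, 100, 600)]))
        p = profile("r", 2017, {"cardiology": 10}, {"cardiology": 9.0})
        assert compute_cmi(p, b) == pytest.approx(1.0)

    def test_pi_doubled_stays(self):
        b = toy_benchmark()
        p = profile(
            "r", 2017, {"cardiology": 30, "long_term_care": 70},
            {"cardiology": 10.0, "long_term_care": 30.0},
        )
        assert compute_pi(p, b) == pytest.approx(2.0)

    def test_pi_one_when_ward_avlos_match(self):
        b = toy_benchmark()
        p = profile(
            "r", 2017, {"cardiology": 30, "long_term_care": 70},
            {"cardiology": 5.0, "long_term_care": 15.0},
        )
        assert compute_pi(p, b) == pytest.approx(1.0)

    def test_self_benchmark_identity_exact(self, two_ward_table):
        """The reference population scored against itself gives CMI = PI = 1."""
        b = build_benchmark(two_ward_table)
        pooled = aggregate(two_ward_table, by=["ward", "year"])
        national = ActivityTable(
            pooled.df.assign(region="Italia"), "pooled"
        )
        p = profile_region(national, "Italia", 2017)
        res = compute_casemix(p, b)
        assert res.cmi == pytest.approx(1.0, abs=1e-12)
        assert res.pi == pytest.approx(1.0, abs=1e-12)
        assert res.coverage == pytest.approx(1.0)

    def test_uniform_efficiency_factor_moves_pi_only(self, two_ward_table):
        """Regional ward AvLOS = e x benchmark ward AvLOS gives PI = e exactly."""
        b = build_benchmark(two_ward_table)
        for e in (0.5, 1.3, 2.0):
            p = profile(
                "r", 2017, {"cardiology": 80, "long_term_care": 20},
                {"cardiology": 5.0 * e, "long_term_care": 15.0 * e},
            )
            assert compute_pi(p, b) == pytest.approx(e, abs=1e-12)

    def test_no_shared_ward_raises(self):
        b = toy_benchmark()
        p = profile("r", 2017, {"oncology": 10}, {"oncology": 8.0})
        with pytest.raises(BenchmarkError):
            compute_cmi(p, b)

    def test_year_mismatch_guarded(self, two_ward_table):
        b = build_benchmark(two_ward_table)
        p = profile("r", 2016, {"cardiology": 10}, {"cardiology": 5.0})
        with pytest.raises(BenchmarkError):
            compute_casemix(p, b)
        res = compute_casemix(p, b, allow_cross_year=True)
        assert res.year == 2016

    def test_partial_coverage_renormalises_and_reports(self):
        b = toy_benchmark()
        p = profile(
            "r", 2017,
            {"cardiology": 60, "oncology": 40},
            {"cardiology": 5.0, "oncology": 8.0},
        )
        with pytest.warns(UserWarning, match="shared"):
            res = compute_casemix(p, b)
        assert res.wards_used == 1
        assert res.coverage == pytest.approx(0.6)
        assert res.cmi == pytest.approx(0.5)  # 5/10 on the shared ward

    def test_regional_denominator_variant(self, two_ward_table):
        """Dividing by the region's own overall AvLOS rescales both indices."""
        b = build_benchmark(two_ward_table)
        p = profile_region(two_ward_table, "north", 2017)
        ratio = b.avlos_all / p.avlos_all
        assert compute_cmi(p, b, "regional") == pytest.approx(
            compute_cmi(p, b) * ratio
        )
        assert compute_pi(p, b, "regional") == pytest.approx(
            compute_pi(p, b) * ratio
        )

    @given(
        n_wards=st.integers(1, 4),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_brute_force_oracle_small_systems(self, n_wards, data):
        """Term-by-term summation written independently matches the module."""
        wards = [f"w{i}" for i in range(n_wards)]
        d_ref = [data.draw(st.integers(1, 500)) for _ in wards]
        los_ref = [data.draw(st.floats(1, 30)) for _ in wards]
        d_str = [data.draw(st.integers(0, 500)) for _ in wards]
        if sum(d_str) == 0:
            d_str[0] = 1
        los_str = [data.draw(st.floats(1, 30)) for _ in wards]

        bench = build_benchmark(
            make_table(
                [
                    ("all", w, 2017, 1.0, d, round(d * l))
                    for w, d, l in zip(wards, d_ref, los_ref)
                ]
            )
        )
        prof = profile(
            "r", 2017,
            dict(zip(wards, d_str)),
            {w: l for w, d, l in zip(wards, d_str, los_str) if d > 0},
        )
        shared = [w for w, d in zip(wards, d_str) if d > 0]
        d_all = sum(prof.discharges_by_ward[w] for w in shared)
        s_all = sum(bench.discharge_share_by_ward[w] for w in shared)
        cmi_bf = sum(
            bench.avlos_by_ward[w] * prof.discharges_by_ward[w] / d_all
            for w in shared
        ) / bench.avlos_all
        pi_bf = sum(
            prof.avlos_by_ward[w] * bench.discharge_share_by_ward[w] / s_all
            for w in shared
        ) / bench.avlos_all
        assert compute_cmi(prof, bench) == pytest.approx(cmi_bf, rel=1e-12)
        assert compute_pi(prof, bench) == pytest.approx(pi_bf, rel=1e-12)

    @given(scale=st.integers(2, 50))
    @settings(max_examples=20, deadline=None)
    def test_cmi_invariant_to_discharge_scaling(self, scale):
        b = toy_benchmark()
        p1 = profile(
            "r", 2017, {"cardiology": 3, "long_term_care": 7},
            {"cardiology": 6.0, "long_term_care": 14.0},
        )
        p2 = profile(
            "r", 2017,
            {"cardiology": 3 * scale, "long_term_care": 7 * scale},
            {"cardiology": 6.0, "long_term_care": 14.0},
        )
        assert compute_cmi(p1, b) == pytest.approx(compute_cmi(p2, b), rel=1e-12)
        # PI ignores the regional mix entirely
        assert compute_pi(p1, b) == pytest.approx(compute_pi(p2, b), rel=1e-12)

    def test_cmi_convexity_bounds(self, two_ward_table):
        b = build_benchmark(two_ward_table)
        lo = min(b.avlos_by_ward.values()) / b.avlos_all
        hi = max(b.avlos_by_ward.values()) / b.avlos_all
        for region in ("north", "south"):
            cmi = compute_cmi(profile_region(two_ward_table, region, 2017), b)
            assert lo <= cmi <= hi


class TestWardDayShare:
    def test_icu_share_of_national_days(self, hospital_activity, icu_activity):
        """ICU inpatient days are 2% of all hospital days in 2017."""
        combined = ActivityTable(
            pd.concat(
                [
                    aggregate(hospital_activity.subset(year=2017), ["ward", "year"]).df,
                    aggregate(icu_activity.subset(year=2017), ["ward", "year"]).df,
                ],
                ignore_index=True,
            )
        )
        share = ward_day_share(combined, "intensive_care")
        assert round(share, 2) == 0.02

    def test_single_ward_system(self):
        t = make_table([("all", "cardiology", 2017, 10, 100, 500)])
        assert ward_day_share(t, "cardiology") == 1.0

    def test_zero_day_ward(self):
        t = make_table(
            [
                ("all", "cardiology", 2017, 10, 100, 500),
                ("all", "oncology", 2017, 10, 0, 0),
            ]
        )
        assert ward_day_share(t, "oncology") == 0.0

    def test_absent_ward_raises(self, icu_activity):
        with pytest.raises(BenchmarkError):
            ward_day_share(icu_activity, "cardiology")


class TestCasemixTable:
    def test_self_consistent_table(self, two_ward_table):
        out = casemix_table(two_ward_table, 2017)
        assert set(out["region"]) == {"north", "south"}
        # discharge-weighted mean of regional CMIs is 1 by construction
        merged = out.set_index("region")
        d = {"north": 200, "south": 200}
        mean_cmi = sum(merged.loc[r, "cmi"] * d[r] for r in d) / sum(d.values())
        assert mean_cmi == pytest.approx(1.0, abs=1e-12)
        assert (out["coverage"] == 1.0).all()
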