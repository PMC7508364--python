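#!/usr/bin/env python
"""Traffic-light screening and complexity/performance quadrants, 2017.

Screens each region's TOI (1-3 days) and BOR (75-85%) and crosses the
published case-mix (CMI) and performance (PI) indices at the benchmark
point (1, 1).  Finding: only Molise breaches both bands (red); Basilicata
and Sardegna breach one (yellow); the other 18 regions are green.  The
quadrants split 6 / 4 / 7 / 4 (complex-efficient / simple-efficient /
complex-inefficient / simple-inefficient).  Writes the classification
report (CSV + markdown) under results/.
"""

from pathlib import Path

from bedmix import (
    classify_regions,
    compute_indicator_table,
    render_report,
)
from bedmix.datasets import load_hospital_activity, load_reported_casemix

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    ind = compute_indicator_table(load_hospital_activity().subset(year=2017))
    ind = ind[ind["region"] != "Total"]
    casemix = load_reported_casemix("all")
    results = classify_regions(ind, casemix)

    (OUT / "classification_2017.csv").write_text(
        render_report(results, ind, casemix, format="csv")
    )
    (OUT / "classification_2017.md").write_text(
        render_report(results, format="markdown")
    )

    for area in ("red", "yellow", "green"):
        regions = sorted(results[results["area"] == area]["region"])
        label = ", ".join(regions) if len(regions) <= 4 else f"{len(regions)} regions"
        print(f"{area:>6}: {label}")
    print(results["quadrant"].value_counts().to_string())
    print("-> classification_2017.csv / .md")


if __name__ == "__main__":
    main()
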