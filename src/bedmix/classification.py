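"""Threshold areas, complexity/performance quadrants, and the report.

Regions are screened against literature reference bands — turnover
interval between 1 and 3 days, occupancy between 75% and 85% — and put in
a traffic-light area: green when both indicators are in band, red when
both are out, yellow otherwise.  Separately, the CMI x PI plane is cut at
1 into four quadrants: CMI >= 1 is a complex case load, PI < 1 is
efficient (shorter stays than the standard).  Both rules operate on
display-rounded values (integer percent for BOR, two decimals otherwise)
with inclusive band edges, so that a region printed at the boundary is
classified as the printed value reads.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import pandas as pd
import yaml

from .rounding import round_half_up

__all__ = [
    "ThresholdConfig",
    "classify_area",
    "classify_quadrant",
    "classify_regions",
    "render_report",
]

AREAS = ("green", "yellow", "red")
QUADRANTS = (
    "complex_efficient",
    "simple_efficient",
    "complex_inefficient",
    "simple_inefficient",
)


@dataclass(frozen=True)
class ThresholdConfig:
    """Reference bands for the traffic-light screening (inclusive)."""

    toi_low: float = 1.0
    toi_high: float = 3.0
    bor_low: float = 75.0
    bor_high: float = 85.0

    def __post_init__(self) -> None:
        if not self.toi_low < self.toi_high:
            raise ValueError("toi_low must be < toi_high")
        if not self.bor_low < self.bor_high:
            raise ValueError("bor_low must be < bor_high")

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        keys = {f for f in ("toi_low", "toi_high", "bor_low", "bor_high")}
        return cls(**{k: float(v) for k, v in raw.items() if k in keys})


def classify_area(
    toi: float, bor: float, cfg: ThresholdConfig = ThresholdConfig()
) -> str:
    """Traffic-light label from rounded TOI (2 d.p.) and BOR (integer %)."""
    toi_r = round_half_up(toi, 2)
    bor_r = round_half_up(bor, 0)
    toi_in = cfg.toi_low <= toi_r <= cfg.toi_high
    bor_in = cfg.bor_low <= bor_r <= cfg.bor_high
    if toi_in and bor_in:
        return "green"
    if not toi_in and not bor_in:
        return "red"
    return "yellow"


def classify_quadrant(cmi: float, pi: float) -> str:
    """Quadrant label from CMI/PI rounded to 2 decimals.

    Boundary convention: CMI >= 1 counts as complex and PI >= 1 as
    inefficient, so a region sitting exactly on the benchmark (1, 1) lands
    in ``complex_inefficient``.
    """
    if cmi <= 0 or pi <= 0:
        raise ValueError("CMI and PI must be positive")
    complex_ = round_half_up(cmi, 2) >= 1.0
    efficient = round_half_up(pi, 2) < 1.0
    return ("complex_" if complex_ else "simple_") + (
        "efficient" if efficient else "inefficient"
    )


def classify_regions(
    indicators: pd.DataFrame,
    casemix: pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Join indicators and indices by region and classify each region.

    ``indicators`` needs columns ``region, toi, bor``; ``casemix`` needs
    ``region, cmi, pi``.  Regions present in only one input are excluded
    and listed in the DataFrame's ``attrs["unmatched"]``.  The output also
    carries ``cmi_pi_ratio`` (rounded CMI over rounded PI), the quantity
    used for map colouring in this kind of report.
    """
    ind = indicators[indicators["region"].notna()].copy()
    cm = casemix.copy()
    merged = ind.merge(cm[["region", "cmi", "pi"]], on="region", how="inner")
    unmatched = sorted(
        set(ind["region"]).symmetric_difference(set(cm["region"]))
    )
    rows = []
    for r in merged.itertuples(index=False):
        toi_r, bor_r = round_half_up(r.toi, 2), round_half_up(r.bor, 0)
        cmi_r, pi_r = round_half_up(r.cmi, 2), round_half_up(r.pi, 2)
        rows.append(
            (
                r.region,
                classify_area(r.toi, r.bor, cfg),
                classify_quadrant(r.cmi, r.pi),
                toi_r,
                bor_r,
                cmi_r,
                pi_r,
                round_half_up(cmi_r / pi_r, 2),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "region",
            "area",
            "quadrant",
            "toi",
            "bor",
            "cmi",
            "pi",
            "cmi_pi_ratio",
        ],
    ).sort_values("region", kind="stable").reset_index(drop=True)
    out.attrs["unmatched"] = unmatched
    return out


def _to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for row in df.itertuples(index=False):
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def render_report(
    results: pd.DataFrame,
    indicators: pd.DataFrame | None = None,
    casemix: pd.DataFrame | None = None,
    format: str = "csv",
) -> str:
    """Render the classification (optionally widened with AvLOS/BTO,
    flags and coverage) as csv, json or markdown text.

    Output is deterministic: fixed column order, regions sorted, display
    rounding already applied by :func:`classify_regions`.
    """
    df = results.copy()
    if indicators is not None:
        extra = [
            c for c in ("avlos", "bto", "flags") if c in indicators.columns
        ]
        if extra:
            df = df.merge(
                indicators[["region", *extra]], on="region", how="left"
            )
            for c in ("avlos", "bto"):
                if c in df.columns:
                    df[c] = df[c].map(
                        lambda x: round_half_up(x, 2) if pd.notna(x) else x
                    )
    if casemix is not None and "coverage" in casemix.columns:
        df = df.merge(casemix[["region", "coverage"]], on="region", how="left")
    df = df.sort_values("region", kind="stable").reset_index(drop=True)
    if format == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    if format == "json":
        return json.dumps(df.to_dict(orient="records"), indent=2, default=str) + "\n"
    if format == "markdown":
        return _to_markdown(df)
    raise ValueError(f"unknown report format {format!r}")
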