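# Methods

## Data model

The unit of observation is the (region, ward, year) aggregate of the
Ministry of Health annual hospital-activity publication: average available
beds over the year, patients discharged in the year, and total inpatient
days. "Beds" is read as the *average daily available* endowment over the
year — the only reading under which occupancy, turnover and stay length
close on the published tables. Records must satisfy non-negativity and
`inpatient_days >= discharges` whenever discharges are positive (every
counted stay lasts at least one day); (region, ward, year) is unique.
Wards a region does not operate are absent rows, never zero rows.

Ward codes come from a controlled vocabulary (the disciplines covering
~90 % of hospitalization complexity, plus `all` for whole-hospital rows);
unknown codes pass with a warning because the ministerial list can extend.
The CSV reader accepts both `.` and `,` decimal marks (Italian sources use
the comma); the writer always emits `.`.

Two packaged fixtures transcribe the published 2010/2017 aggregates (all
wards, and the intensive-care ward, 21 regions each), plus the published
2017 regional CMI/PI columns; every national total in the fixtures
reproduces the printed totals exactly.

## Indicators

With beds *B*, discharges *D*, inpatient days *G*, period *T* days:
BOR = 100·G/(B·T), AvLOS = G/D, TOI = (B·T − G)/D, BTO = D/B.

- **Period.** `period_days` defaults to 365 — the unique value that
  reproduces the published indicator tables from the published inputs —
  and is configurable for leap years.
- **Rounding.** Display rounding is half-away-from-zero: BOR to integer
  percent, everything else to two decimals, matching the published
  precision. All composition uses unrounded values; the identities
  TOI = T/BTO − AvLOS and AvLOS = (BOR/100)·T/BTO hold to 1e−9 on every
  computed row.
- **Degenerate rows.** Zero discharges yield flagged undefined AvLOS/TOI
  (not zeros, which would fake efficiency); zero beds flag BOR/BTO.
  Occupancy above the endowment (BOR > 100, TOI < 0) is representable and
  flagged, never clamped — surge analysis needs it.
- Percent differences between years are 100·(v₁ − v₀)/v₀, undefined at a
  zero baseline. Surge occupancy is a pandemic ICU census over a
  reference-year ICU endowment, in percent, flagged `saturated` at ≥100 %;
  it deliberately ignores non-pandemic ICU patients, so it understates
  total pressure.

## Case-mix and performance indices

Both indices are weighted means of ward-level mean stays divided by the
reference overall mean stay: CMI values the unit's discharge mix at the
*reference* ward AvLOS; PI values the *unit's* ward AvLOS at the reference
discharge mix. The reference is the aggregate of all units in the same
year (cross-year standardisation requires an explicit flag).

Design choices where the definition is genuinely open:

- **Denominator.** The normative form divides both indices by the
  reference overall AvLOS; a variant seen in worked presentations divides
  by the unit's own overall AvLOS instead. The former is the default,
  the latter is available as `denominator="regional"`. They differ by the
  factor `L_ALL^REF / L_ALL^STR`.
- **Partial ward overlap.** Wards present in only one of unit/reference
  are excluded and the weights renormalised over the shared set, keeping
  each index interpretable as a weighted mean; `coverage` reports the
  unit discharge share retained, and a warning fires when it is below 1.
- **Ward day-share.** The share of reference inpatient days spent in one
  ward (e.g. ICU ≈ 0.02 of national days in 2017) is provided as the
  complexity-weight reference statistic; the denominator is the explicit
  `all` row when present, else the sum of ward rows.

Exact properties, all under test: self-benchmark identity (CMI = PI = 1),
CMI invariance to uniform discharge scaling, PI independence from the
unit's mix, PI = e under a uniform ward-AvLOS multiplier e, and the
convexity bounds min_j L_j^REF/L_ALL^REF ≤ CMI ≤ max_j L_j^REF/L_ALL^REF.

## Classification

Thresholds are applied to *display-rounded* values with inclusive bounds:
a region printed at 85 % (unrounded 85.2 %) must classify as the table
reads, so rounding-first is the only consistent rule. Green: both TOI and
BOR in band; red: both out; yellow: exactly one out — an exhaustive,
exclusive partition for any finite inputs. Quadrants cut the rounded
CMI × PI plane with the convention CMI ≥ 1 = complex, PI ≥ 1 =
inefficient, chosen so that boundary units (CMI or PI printing as 1.00)
land with the high-complexity / low-performance clusters respectively;
the exact benchmark point (1, 1) is therefore `complex_inefficient`. The
four published macro-clusters are exactly these quadrants with the area
colour carried alongside; no statistical clustering is involved. The
report also emits the rounded CMI/PI ratio used for map colouring.

## Synthetic generator

`generate_system` emulates the aggregate structure the analysis assumes,
with ground truth:

- each of `n_regions` regions discharges `discharges_per_region` patients
  (default 20 000, a mid-sized region's annual ICU+acute mix at the toy
  five-ward scale) into wards drawn from the national mix tilted toward
  long-stay wards by `t_r ≥ 0` (weight ∝ mix_j · L_j^{t_r});
- stay lengths are shifted Poisson, LOS = 1 + Poisson(e_r·L_j − 1) —
  the simplest integer law with mean exactly e_r·L_j and support ≥ 1;
  means below 1 are rejected at validation;
- ward bed pools are `ceil(expected days / (T · target_bor/100))`
  (default target 79 %, the national all-ward occupancy), so realised
  BOR sits slightly *below* target — a documented ceiling bias covered by
  tolerance bands in the recovery tests;
- one `numpy` Generator seeded from the params drives everything:
  identical params give byte-identical stay logs and aggregates.

The default ward panel spans base mean stays of 4–14 days (the range the
national per-ward tables show) with a mix dominated by medicine/surgery.
The truth object carries e_r (the region's true PI against an
efficiency-1 reference) and closed-form expected CMI/PI against the
pooled benchmark; the expected PI equals e_r exactly only when the
discharge-weighted mean efficiency of the pool is 1, which the recovery
configurations use. What the generator does **not** model: within-year
arrival dynamics, bed blocking, seasonality, transfers, or any epidemic
process — passing recovery tests shows the standardisation algebra and
aggregation are correct, not that real hospital data meet the model's
independence assumptions.

Recovery performance at the default study scale (50 000 discharges/region,
20 seeds): mean recovered PI within 0.1 % of truth, per-seed within
~0.3 %; CMI matches its closed form to the same order; realised BOR within
[72, 78] at target 75.

## Numerical choices and limitations

- Benchmark construction rejects wards with inpatient days but zero
  discharges (an inconsistent aggregate) and drops fully empty wards.
- Share sums and the share-weighted AvLOS consistency of a benchmark are
  enforced to 1e−9.
- The acceptance script and analysis drivers run on the packaged
  2010/2017 aggregates (21 regions × 2 years per table) — desk scale; the
  synthetic validation uses 4–6 regions × 50 000 discharges, the size at
  which sampling error is comfortably below the 1 % recovery criterion.
- Regional CMI/PI for the real 2017 system are not recomputable from the
  packaged aggregates (that would need per-ward per-region microdata);
  the published indices are shipped as data and the index machinery is
  validated synthetically instead.
- The published ICU cluster prose lists one region in two clusters; the
  deterministic quadrant rule here yields exactly one label per region,
  and no attempt is made to reproduce that ambiguity.
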