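# medaccess

Availability, price and affordability of essential medicines, computed from
hospital drug-procurement panels in the WHO/HAI survey tradition — for
pharmaco-epidemiologists and health-policy analysts who have procurement
records rather than shelf surveys.

The package implements three access indicators over a panel of hospitals
(secondary/tertiary tiers, provinces grouped into eastern/central/western
regions), a basket of surveyed medicines, and monthly purchase lines from
2011 to 2016:

- **Availability** of medicine *d* in stratum *s* and year *t*:
  `A = 100 · #{panel hospitals with ≥1 procurement record of d} / #panel`,
  with the roster as an explicit denominator (hospitals with no records
  still count). Basket summaries are medians over medicines, and the
  *product-specific Δ* between adjacent years is the median over medicines
  of each medicine's change.
- **Median price ratio**: `MPR = median local unit price / IRP`, where all
  strengths of a chemical are normalized to a price per reference unit
  (per-mg price rescaled to one declared reference strength), the
  international reference price (IRP, USD, 2011–2013) is converted to CNY by
  purchasing-power-parity rates, and 2014–2016 local prices are deflated to
  the 2013 basis with discount factors `DF(y) = (1+r)^(2013−y)` before
  comparison against the 2013 IRP. An MPR of 2 means the local price is
  twice the reference price; ≤1 indicates efficient procurement. Medians
  are two-level: hospital median first, then the median across hospitals.
- **Catastrophic drug expenditure (CDE)**: for a chronic treatment costing
  `c` CNY/year (unit price × DDD units/day × 365), the incidence at budget
  share τ is `100 · F(c/τ)`, the fraction of the population whose per-capita
  income is at most `c/τ`. `F` is reconstructed from grouped yearbook-style
  income tables (urban/rural, per year) by a lognormal fit to the group
  means or a piecewise-uniform/Pareto-tail reconstruction. τ = 10% is the
  headline threshold, with 7.5% and 12.5% sensitivity.

Group contrasts (innovator brand vs generic; the three regions) use the
Wilcoxon rank-sum test (exact by enumeration for small tie-free samples)
and the Kruskal–Wallis test with midranks and tie correction.

Because real national procurement databases are proprietary, the package
ships a seeded synthetic-panel generator (`medaccess.simulate`) with
analytic ground truth — per-stratum stocking probabilities, true median
prices as multiples of the IRP, lognormal incomes — so every stage is
testable end to end.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic conditions (seed 42: 396 secondary + 763 tertiary hospitals, 28
provinces, 30 medicines, ~0.9M purchase lines):

```
python analysis/01_simulate.py
python analysis/02_availability.py
python analysis/03_pricing.py
python analysis/04_affordability.py
```

`02_availability.py` prints, among other things:

```
median availability (%) by year and region:
region  central  eastern  nationwide  western
year
2011       35.9     60.4        46.1     39.9
2012       45.5     64.8        53.8     46.1
2013       39.7     60.6        48.0     41.1
```

— the basket median availability per stratum-year: e.g. in 2013 half the 30
medicines were stocked by at least 48% of the 1,159 panel hospitals, with
the eastern region well above central/western (the configured regional
disparity, recovered by the pipeline). `03_pricing.py` prints the median
MPR grid and the brand contrast, ending with the published
innovator/generic ratio column recomputed from its published basket
medians:

```
  2011: 29.51 / 8.06 = 3.66
  2016: 34.76 / 5.50 = 6.32
```

`04_affordability.py` prints the income-distribution fits (exact on the
analytic quintile tables, rms residual ~1e-11) and the CDE grid; e.g. at
the 10% threshold in 2011, generic metformin shows 65.5% rural vs 3.7%
urban incidence — rural populations, with lower incomes, are far more
exposed — and incidence falls over 2011–2014 as incomes grow. Tables land
in `results/`.

The same steps are available as a CLI for externally supplied CSVs
(schemas: `records.csv` with one purchase line per row; `panel.csv` the
hospital roster; `drugs.csv` the medicine definitions; `irp.csv`,
`ppp.csv`, `df.csv` the reference basis; `income.csv` the grouped income
tables — `medaccess simulate --outdir d/` writes examples of all of them):

```
medaccess simulate --seed 42 --outdir data/
medaccess availability --records data/records.csv --panel data/panel.csv \
    --drugs data/drugs.csv --out avail.csv
medaccess mpr --records data/records.csv --drugs data/drugs.csv \
    --basis-dir data --out mpr.csv
medaccess cde --prices prices.csv --income data/income.csv \
    --drugs data/drugs.csv --out cde.csv
```

Malformed record rows never abort a run; they are diverted to a
line-numbered rejects report.

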