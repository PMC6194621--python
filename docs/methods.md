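# Methods

## Scope and data model

The pipeline measures three access-to-medicines indicators over hospital
procurement panels: facility availability, median price ratios (MPR), and
the incidence of catastrophic drug expenditure (CDE). The unit of
observation is a purchase line (hospital, month, medicine, brand status,
strength, pack size, pack price). The hospital roster is a separate input:
availability denominators come from the roster, never from the records, so
hospitals that stop purchasing still count. Rows violating schema
invariants (nonpositive prices, out-of-range dates, unknown brand status)
are diverted to a line-numbered rejects report instead of aborting —
observational procurement data is dirty, and partial failure must be
visible, not fatal.

Provinces map to eastern/central/western regions through a packaged table
following the standard Chinese statistical grouping (28 provinces; an
override mapping can be supplied).

## Smallest-unit price normalization

All strengths of one chemical are pooled by normalizing each line to a
price per *reference unit*: `(pack_price / pack_size)` is the price of one
smallest unit (tablet, vial, puff) at the line's strength; dividing by the
strength expressed in the drug's reference unit gives a per-mg (or
per-activity-unit) price, and multiplying by the declared reference
strength yields the comparable unit price. The reference strength and unit
are per-drug configuration: for forms whose natural unit is not mass-of-
moiety-per-tablet (inhalers, injectables, insulins) the convention is
declared in the drug table rather than guessed. Mass units interconvert
(g/mg/µg/ng); activity units (IU) convert only to themselves, and a
mismatch is an error naming both units.

## Availability

"Available" means at least one procurement record within the window; the
default window is the calendar year (procurement data observes purchasing,
not shelf stock, so presence-in-the-year is the weakest defensible proxy;
the window is configurable). Availability is
`100 × stocking hospitals / panel hospitals` per stratum (year × region ×
tier × brand status). Brand-specific availability keeps the full panel
denominator, not the hospitals stocking either version.

Basket summaries use the median across medicines with the mean-of-central-
pair convention for even counts. The product-specific Δ between adjacent
years is the median across medicines of each medicine's change; medicines
absent from either year are excluded and counted. Nationwide values are not
medians of regional medians: stocking counts add across regions, so the
nationwide percentage is the panel-size-weighted combination (asserted in
tests).

## Pricing

The reference basis holds per-unit international reference prices (USD,
2011–2013), PPP conversion rates (CNY per international dollar, per year),
and discount factors. The IRP in CNY for year *y* ≤ 2013 is
`IRP_USD(y) × PPP(y)`. Reference prices do not exist after 2013, so local
prices from 2014–2016 are deflated to the 2013 price level —
`DF(y) = (1+r)^(2013−y)`, default r = 0.03/yr, or an explicit per-year DF
table — and compared against the 2013 CNY reference price. DF(2013) is
exactly 1 by contract. Price batches carry a `basis` flag ("nominal" vs
"2013") and deflation refuses an already-deflated batch: double discounting
is a silent, order-of-magnitude-compounding error, so it is made loud.

Stratum medians are two-level by default: each hospital contributes the
median of its own transactions, and the stratum value is the median across
hospitals — the facility-level convention of shelf-survey methodology,
which keeps high-volume hospitals from dominating. A `transactions` mode
pools all lines for sensitivity. Reported figures are rounded half-to-even
at two decimals at the reporting layer only; internal math is full
precision.

## Affordability

Treatment cost uses the defined daily dose: daily cost = unit price ×
(DDD / reference strength), annualized over 365 days (the treatments are
lifelong daily regimens; the day count is a constant, not a parameter worth
fitting). Drug expenditure is pre-reimbursement, which makes regions with
different reimbursement schedules comparable.

Income distributions are reconstructed from grouped tables (population
shares with group mean incomes, per year and urban/rural sector). Two
methods:

- **lognormal** (default): minimize the squared relative error of the
  observed group means against the analytic conditional means of a
  lognormal between the share-defined quantile cut points,
  `E[X | q_{i-1} < F(X) ≤ q_i] = e^{μ+σ²/2}(Φ(Φ⁻¹(q_i)−σ) − Φ(Φ⁻¹(q_{i-1})−σ))/(q_i−q_{i-1})`,
  via Nelder–Mead on (μ, log σ). σ can be held fixed (a single-group table
  cannot identify it). A residual above tolerance is recorded as a warning
  in the fitted parameters, not raised.
- **piecewise**: each non-top group's mass is uniform on an interval
  centered on its mean with half-width 45% of the smaller gap to the
  neighbouring means — group means are reproduced exactly and intervals
  stay disjoint (the implied density has gaps, a mild artefact of grouped
  data); the top group is a Pareto tail with its lower bound at the
  midpoint of the last two means and shape matched to the top mean. This
  serves tables too coarse to support a parametric fit.

CDE incidence at threshold τ is `100 · F(c/τ)`: the fraction whose budget
share `c/income` is τ *or more* (the boundary counts). Incidence is zero at
zero cost by definition. The budget share compares annual cost to annual
per-capita income; an optional household-size divisor rescales to household
terms. Thresholds 7.5%/10%/12.5% give a built-in sensitivity band, and
incidence is non-increasing in τ by construction — a published grid
violating that ordering indicates a table defect, not a valid observation,
and this pipeline will not emulate one.

## Rank tests

Brand and regional contrasts are distribution-free. The two-sample Wilcoxon
rank-sum uses midranks for ties; the p-value is exact by enumerating all
C(n, n1) rank assignments when n1+n2 ≤ 12 and the pooled data is tie-free,
otherwise a normal approximation with tie correction and a 0.5 continuity
correction (configurable). The k-sample regional comparison is
Kruskal–Wallis with tie correction against χ²(k−1); for k = 2 it agrees
with the two-sided rank-sum normal approximation without continuity. The
sampling unit fed to the tests is the per-medicine stratum value; group
membership comes from the input table. No multiple-testing correction is
applied. An independent implementation (scipy's `mannwhitneyu`/`kruskal`)
serves as a cross-check oracle in the tests; the shipped statistics are
computed by this module.

## Synthetic study conditions

The generator emulates the structure of a national procurement panel with
known truth. Defaults (the study conditions; `default_config(seed)`):

- Panel: 396 secondary + 763 tertiary hospitals spread round-robin over 28
  provinces; years 2011–2016.
- Stocking: hospital × drug × brand × year Bernoulli. Per-drug base odds
  are lognormally spread around 0.40 (with a fast-moving antibiotic pinned
  high at 0.82 and a near-obsolete sulfonylurea at 0.03); odds multipliers:
  eastern 1.75, central 0.80, western 0.90; generic 1.35 vs innovator 0.62;
  year wiggle 0.82–1.35. This puts the median any-brand availability near
  50% with a clear eastern advantage.
- Purchases: each stocked hospital-drug-year emits a zero-truncated
  Poisson(λ = 6, capped at 12) number of monthly lines in distinct months;
  unit prices are lognormal with σ_p = 0.2 around the true median
  level × IRP_CNY, spread over 1× and 2× reference strengths and varied
  pack sizes so the normalization is exercised.
- Prices: generic levels (multiples of the IRP) lognormal around 4.2 (one
  inhaled corticosteroid pinned at 80, one cheap H2 blocker at 0.9);
  innovator/generic ratio lognormal around 4.5; region multipliers eastern
  1.9, central 0.88, western 0.92; a 1.35 level jump in 2016. Post-2013
  prices drift up at the configured inflation (3%/yr), and the generated
  discount factors are consistent with it, so the true MPR equals the
  configured level in every year.
- Incomes: lognormal; urban μ 9.99 → 10.26 (σ = 0.50), rural μ 8.85 → 9.18
  (σ = 0.62) over 2011–2014 — urban incomes roughly 3× rural, both growing.
  Grouped tables are exact analytic quintile means, so fit-recovery tests
  carry no Monte-Carlo noise.
- IRPs: one lognormal draw per drug (median ≈ $0.06/unit), constant
  2011–2013; PPP ≈ 3.5–3.7 CNY per international dollar.

These magnitudes echo published national-survey scales (availability in the
40s–50s, generic MPR baskets of a few, innovator/generic ratios of 4–6) for
demonstration; tests compare pipeline output against the generator's own
analytic truth, never against those echoes.

What the generator does *not* model — and what passing tests therefore do
not establish about real data: correlated stocking between the brand
versions of a drug (real hospitals often procure exactly one of each, which
the independence assumption misses, inflating any-brand availability),
hospital-level price heterogeneity beyond lognormal noise, within-year
stocking gaps, entry/exit of hospitals, basket composition shifts, and any
behavioural response of procurement to policy.

## Numerical choices and recovery regimes

- Medians everywhere use the mean-of-central-pair convention; numpy's
  `median` provides it.
- The end-to-end MPR recovery guarantee (2% relative) applies where at
  least 200 hospitals contribute prices to a stratum at σ_p = 0.2: the
  sampling error of a median over n hospital medians scales as
  ≈ 1.25 σ_p/√(kn), so thinly stocked strata are excluded from that claim
  rather than silently widening it.
- Availability recovery is judged against 99% binomial intervals at the
  stratum panel size (regional heterogeneity makes the count
  Poisson-binomial; the binomial interval at the weighted mean is slightly
  conservative).
- CDE recovery compares the pipeline's incidence (distribution refitted
  from grouped tables) against the lognormal closed form
  `100 · Φ((ln(c/τ) − μ)/σ)` at the same annual cost, isolating the
  reconstruction error; the cost estimate's error is bounded separately by
  the MPR check.
- Nelder–Mead on (μ, log σ) with tight tolerances recovers analytic
  quintile parameters to ~1e-5; the log-σ parameterization keeps the search
  unconstrained.
- Degenerate inputs: empty strata, empty baskets and empty samples raise;
  all-identical samples give p = 1; zero-variance normal approximations are
  short-circuited.

## Analysis scale

The shipped drivers and the acceptance script run the full default panel
(1,159 hospitals × 30 drugs × 2 brands × 6 years, ~0.9M purchase lines,
seconds to generate); unit tests use shrunken panels (tens of hospitals,
1–4 drugs) with the same code paths. Interval-coverage and test-size
checks use 200 replicate panels and 2,000 null simulations respectively.

## Known limitations

- The regional k-sample test choice (Kruskal–Wallis) is an assumption; the
  survey literature often reports a regional P without naming the test.
- Whether published basket medians pool transactions or facilities is not
  always stated; both are implemented, facility-level is the default.
- Injectable/inhaler unitization is per-drug configuration; comparisons
  across packages hinge on consistent reference-unit declarations.
- Per-capita (not household) income is the default CDE denominator; the
  household multiplier is a blunt rescaling, not a household-composition
  model.
- The discount-rate default (3%/yr) is a convention; an explicit DF table
  should be preferred when the deflation series used by a data provider is
  known.
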