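"""Synthetic procurement panels, reference bases and grouped income tables.

The generator emulates the structure of a national hospital drug-procurement
panel — 396 secondary and 763 tertiary public hospitals in 28 provinces
grouped into eastern/central/western regions, 30 surveyed medicines with
innovator-brand and generic versions, monthly purchase lines 2011-2016 —
with *known ground truth*: per-stratum stocking probabilities, true median
unit prices (lognormal price noise around a level expressed as a multiple of
the international reference price), and lognormal income distributions whose
grouped tables are computed analytically.  Every pipeline stage is therefore
testable against closed forms without any external data.

Stocking of each hospital x drug x brand x year is Bernoulli; stocked pairs
emit a zero-truncated-Poisson number of monthly purchase lines whose pack
price encodes a lognormal unit price, spread over random strengths and pack
sizes so the smallest-unit normalization is exercised.  Prices after 2013
carry a configurable inflation consistent with the discount factors of the
generated reference basis, so the true MPR equals the configured level in
every year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .affordability import IncomeGroupTable, lognormal_group_means
from .pricing import BASE_YEAR, ReferenceBasis
from .records import (
    BRAND_STATUSES,
    DrugDefinition,
    PROVINCE_REGION,
    REGIONS,
    write_drug_definitions,
    write_records,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_drugs",
    "default_config",
    "generate_panel",
    "generate_income_tables",
    "generate_reference_basis",
    "write_dataset",
    "AFFORDABILITY_DRUGS",
]

YEARS = (2011, 2012, 2013, 2014, 2015, 2016)
INCOME_YEARS = (2011, 2012, 2013, 2014)
SECTORS = ("urban", "rural")

#: the four treatments (hypertension, rheumatoid arthritis, diabetes) whose
#: lifelong daily cost feeds the catastrophic-expenditure analysis
AFFORDABILITY_DRUGS = ("hydrochlorothiazide", "nifedipine", "diclofenac", "metformin")

# drug_id, class, disorder, on_neml, ref strength, unit, DDD, unit
_DRUG_ROWS = [
    ("amoxicillin", "antibiotic", "acute", True, 250, "mg", 1500, "mg"),
    ("azithromycin", "antibiotic", "acute", True, 250, "mg", 300, "mg"),
    ("cefuroxime", "antibiotic", "acute", True, 250, "mg", 500, "mg"),
    ("ceftriaxone", "antibiotic", "acute", True, 1000, "mg", 2000, "mg"),
    ("ciprofloxacin", "antibiotic", "acute", True, 250, "mg", 1000, "mg"),
    ("doxycycline", "antibiotic", "acute", True, 100, "mg", 100, "mg"),
    ("clarithromycin", "antibiotic", "acute", False, 250, "mg", 500, "mg"),
    ("paracetamol", "analgesic", "acute", True, 500, "mg", 3000, "mg"),
    ("ibuprofen", "analgesic", "acute", True, 200, "mg", 1200, "mg"),
    ("diclofenac", "analgesic", "chronic", True, 25, "mg", 100, "mg"),
    ("tramadol", "analgesic", "acute", True, 50, "mg", 300, "mg"),
    ("omeprazole", "gastrointestinal", "acute", True, 20, "mg", 20, "mg"),
    ("ranitidine", "gastrointestinal", "acute", True, 150, "mg", 300, "mg"),
    ("metronidazole", "gastrointestinal", "acute", True, 200, "mg", 2000, "mg"),
    ("hydrochlorothiazide", "antihypertensive", "chronic", True, 25, "mg", 25, "mg"),
    ("nifedipine", "antihypertensive", "chronic", True, 10, "mg", 30, "mg"),
    ("captopril", "antihypertensive", "chronic", True, 25, "mg", 50, "mg"),
    ("amlodipine", "antihypertensive", "chronic", True, 5, "mg", 5, "mg"),
    ("simvastatin", "lipid_lowering", "chronic", True, 20, "mg", 30, "mg"),
    ("metformin", "antidiabetic", "chronic", True, 500, "mg", 2000, "mg"),
    ("glibenclamide", "antidiabetic", "chronic", True, 5, "mg", 10, "mg"),
    ("gliclazide", "antidiabetic", "chronic", True, 80, "mg", 160, "mg"),
    ("insulin_nph", "antidiabetic", "chronic", True, 100, "IU", 40, "IU"),
    ("salbutamol", "respiratory", "acute", True, 0.1, "mg", 0.8, "mg"),
    ("beclometasone", "respiratory", "chronic", True, 0.25, "mg", 0.8, "mg"),
    ("aminophylline", "respiratory", "acute", True, 100, "mg", 600, "mg"),
    ("diazepam", "neuropsychiatric", "acute", True, 5, "mg", 10, "mg"),
    ("phenytoin", "neuropsychiatric", "chronic", True, 100, "mg", 300, "mg"),
    ("loratadine", "antihistamine", "acute", False, 10, "mg", 10, "mg"),
    ("fluconazole", "antifungal", "acute", False, 50, "mg", 200, "mg"),
]

_DOSAGE_FORM = {
    "ceftriaxone": "vial", "insulin_nph": "vial",
    "salbutamol": "inhaler", "beclometasone": "inhaler",
    "aminophylline": "injection",
}

#: PPP conversion rates, CNY per international dollar
DEFAULT_PPP = {2011: 3.696, 2012: 3.506, 2013: 3.545}


def default_drugs() -> list[DrugDefinition]:
    """The 30-medicine survey basket: 10 therapeutic classes, 18 acute and
    12 chronic treatments, 27 on the essential-medicines list."""
    return [
        DrugDefinition(d, cls, dis, neml, float(rv), ru, float(dv), du)
        for d, cls, dis, neml, rv, ru, dv, du in _DRUG_ROWS
    ]


@dataclass
class SimulationConfig:
    """Complete parameterization of one synthetic study.

    ``stocking_prob`` and ``price_level`` are tidy tables over
    drug x region x brand x year: the Bernoulli stocking probability and the
    true median unit price as a multiple of the drug's CNY reference price.
    ``price_sigma`` is the lognormal dispersion of individual purchase-line
    unit prices around the true median; ``inflation`` drifts post-2013 prices
    upward and fixes the generated discount factors.  The seed fully
    determines all output.
    """

    seed: int
    n_secondary: int = 396
    n_tertiary: int = 763
    province_region: Mapping[str, str] = field(default_factory=lambda: dict(PROVINCE_REGION))
    years: tuple[int, ...] = YEARS
    drugs: list[DrugDefinition] = field(default_factory=default_drugs)
    stocking_prob: pd.DataFrame | None = None
    price_level: pd.DataFrame | None = None
    price_sigma: float = 0.2
    monthly_lambda: float = 6.0
    inflation: float = 0.03
    income_params: dict[tuple[int, str], tuple[float, float]] = field(default_factory=dict)
    income_groups: int = 5
    irp_usd: dict[str, float] = field(default_factory=dict)
    ppp_rate: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PPP))

    def __post_init__(self) -> None:
        if self.price_sigma <= 0 or self.monthly_lambda <= 0:
            raise ValueError("dispersions must be positive")
        if self.stocking_prob is not None:
            p = self.stocking_prob["p"]
            if ((p < 0) | (p > 1)).any():
                raise ValueError("stocking probabilities must lie in [0, 1]")
        if self.price_level is not None and (self.price_level["level"] <= 0).any():
            raise ValueError("price levels must be positive")

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions: a paper-scale panel with regionally
    disparate availability and prices.

    Availability is spread across drugs (a few percent up to ~85%), higher in
    the eastern region, higher for generics than innovator brands, and
    wiggles year on year.  Generic price levels sit around 5-8x the reference
    price with innovator brands roughly 4-5x dearer; the eastern region is
    the most expensive.  Incomes are lognormal, urban above rural, growing
    through 2011-2014.
    """
    cfg = SimulationConfig(seed=seed)
    rng = np.random.default_rng([seed, 10_101])
    drug_ids = cfg.drug_ids
    n_drugs = len(drug_ids)

    # base odds 0.40: with the brand effects below this puts the median
    # any-brand availability near 50% (generic ~0.35, innovator ~0.20)
    base_logit = rng.normal(np.log(0.40), 1.0, size=n_drugs)
    overrides = {"azithromycin": 0.82, "metformin": 0.80, "glibenclamide": 0.03}
    for k, v in overrides.items():
        base_logit[drug_ids.index(k)] = np.log(v / (1 - v))
    region_odds = {"eastern": 1.75, "central": 0.80, "western": 0.90}
    brand_odds = {"generic": 1.35, "innovator_brand": 0.62}
    year_odds = dict(zip(YEARS, (1.00, 1.35, 1.02, 0.82, 1.28, 0.85)))

    gen_level = np.exp(rng.normal(np.log(4.2), 0.8, size=n_drugs))
    gen_level[drug_ids.index("beclometasone")] = 80.0
    gen_level[drug_ids.index("ranitidine")] = 0.9
    ib_ratio = np.exp(rng.normal(np.log(4.5), 0.3, size=n_drugs))
    region_price = {"eastern": 1.9, "central": 0.88, "western": 0.92}
    year_price = dict(zip(YEARS, (1.00, 0.97, 0.99, 0.96, 0.94, 1.35)))

    rows = []
    for i, drug in enumerate(drug_ids):
        for region in REGIONS:
            for brand in BRAND_STATUSES:
                for year in YEARS:
                    logit = (base_logit[i] + np.log(region_odds[region])
                             + np.log(brand_odds[brand]) + np.log(year_odds[year]))
                    p = float(np.clip(1 / (1 + np.exp(-logit)), 0.01, 0.99))
                    level = gen_level[i] * (ib_ratio[i] if brand == "innovator_brand" else 1.0)
                    level *= region_price[region] * year_price[year]
                    rows.append({
                        "drug_id": drug, "region": region, "brand_status": brand,
                        "year": year, "p": p, "level": float(level),
                    })
    grid = pd.DataFrame(rows)
    cfg.stocking_prob = grid[["drug_id", "region", "brand_status", "year", "p"]]
    cfg.price_level = grid[["drug_id", "region", "brand_status", "year", "level"]]

    cfg.irp_usd = dict(zip(drug_ids, np.exp(rng.normal(np.log(0.06), 1.0, size=n_drugs))))

    # per-capita disposable income, CNY/year: urban ~e^9.99 (22k) growing 9%/yr,
    # rural ~e^8.85 (7k) growing 11%/yr, with wider rural dispersion
    for j, year in enumerate(INCOME_YEARS):
        cfg.income_params[(year, "urban")] = (9.99 + 0.09 * j, 0.50)
        cfg.income_params[(year, "rural")] = (8.85 + 0.11 * j, 0.62)
    return cfg


@dataclass
class GroundTruth:
    """Analytic truth implied by a :class:`SimulationConfig`.

    ``stocking`` and ``price`` are the config grids; ``price`` additionally
    carries the true median unit price in current CNY
    (level x IRP_cny x inflation drift) and the true MPR (= level).
    """

    stocking: pd.DataFrame
    price: pd.DataFrame
    income: dict[tuple[int, str], tuple[float, float]]
    region_hospitals: dict[str, int]
    inflation: float

    def true_availability(
        self, drug_id: str, year: int, brand_status: str = "all",
        region: str | None = None,
    ) -> float:
        """True stocking probability; brand "all" combines the independently
        drawn innovator and generic Bernoullis, nationwide weights regions by
        panel size."""
        if region is None:
            total = sum(self.region_hospitals.values())
            return sum(
                self.true_availability(drug_id, year, brand_status, r) * n / total
                for r, n in self.region_hospitals.items()
            )
        sub = self.stocking[
            (self.stocking["drug_id"] == drug_id)
            & (self.stocking["year"] == year)
            & (self.stocking["region"] == region)
        ]
        p = dict(zip(sub["brand_status"], sub["p"]))
        if brand_status == "all":
            return 1.0 - (1.0 - p["innovator_brand"]) * (1.0 - p["generic"])
        return p[brand_status]

    def true_mpr(self, drug_id: str, year: int, brand_status: str, region: str) -> float:
        sub = self.price[
            (self.price["drug_id"] == drug_id) & (self.price["year"] == year)
            & (self.price["region"] == region)
            & (self.price["brand_status"] == brand_status)
        ]
        return float(sub["level"].iloc[0])

    def true_median_price(self, drug_id: str, year: int, brand_status: str, region: str) -> float:
        sub = self.price[
            (self.price["drug_id"] == drug_id) & (self.price["year"] == year)
            & (self.price["region"] == region)
            & (self.price["brand_status"] == brand_status)
        ]
        return float(sub["true_median_unit_price"].iloc[0])

    def cde_closed_form(
        self, annual_cost: float, year: int, sector: str, threshold: float
    ) -> float:
        """Exact incidence under the true lognormal income distribution:
        100 * Phi((ln(cost/threshold) - mu) / sigma)."""
        mu, sigma = self.income[(year, sector)]
        if annual_cost <= 0:
            return 0.0
        return 100.0 * float(stats.norm.cdf((np.log(annual_cost / threshold) - mu) / sigma))


def _build_panel(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic hospital roster: both tiers spread round-robin over the
    28 provinces."""
    provinces = sorted(cfg.province_region)
    rows = []
    hid = 0
    for tier, n in (("secondary", cfg.n_secondary), ("tertiary", cfg.n_tertiary)):
        for i in range(n):
            hid += 1
            prov = provinces[i % len(provinces)]
            rows.append({
                "hospital_id": f"H{hid:04d}", "tier": tier,
                "province": prov, "region": cfg.province_region[prov],
            })
    return pd.DataFrame(rows)


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (redraw zeros)."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def generate_panel(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the full procurement panel.

    Returns ``(records, panel, truth)``: the purchase-line table, the
    hospital roster, and the analytic ground truth.  Identical config and
    seed give identical output.
    """
    if cfg.stocking_prob is None or cfg.price_level is None:
        raise ValueError("config lacks stocking_prob/price_level grids; "
                         "use default_config() or fill them in")
    rng = np.random.default_rng([cfg.seed, 20_202])
    panel = _build_panel(cfg)
    drug_ids = cfg.drug_ids
    years = list(cfg.years)
    regions = list(REGIONS)
    brands = list(BRAND_STATUSES)

    d_idx = {d: i for i, d in enumerate(drug_ids)}
    r_idx = {r: i for i, r in enumerate(regions)}
    b_idx = {b: i for i, b in enumerate(brands)}
    y_idx = {y: i for i, y in enumerate(years)}

    p_arr = np.zeros((len(drug_ids), len(regions), len(brands), len(years)))
    lvl_arr = np.zeros_like(p_arr)
    for row in cfg.stocking_prob.itertuples(index=False):
        p_arr[d_idx[row.drug_id], r_idx[row.region], b_idx[row.brand_status], y_idx[row.year]] = row.p
    for row in cfg.price_level.itertuples(index=False):
        lvl_arr[d_idx[row.drug_id], r_idx[row.region], b_idx[row.brand_status], y_idx[row.year]] = row.level

    # cartesian hospital x drug x brand x year
    n_h, n_d, n_b, n_y = len(panel), len(drug_ids), len(brands), len(years)
    h = np.repeat(np.arange(n_h), n_d * n_b * n_y)
    d = np.tile(np.repeat(np.arange(n_d), n_b * n_y), n_h)
    b = np.tile(np.repeat(np.arange(n_b), n_y), n_h * n_d)
    y = np.tile(np.arange(n_y), n_h * n_d * n_b)
    hreg = panel["region"].map(r_idx).to_numpy()[h]
    p_combo = p_arr[d, hreg, b, y]
    stocked = rng.random(p_combo.size) < p_combo
    h, d, b, y, hreg = h[stocked], d[stocked], b[stocked], y[stocked], hreg[stocked]
    m = h.size

    k = np.minimum(_truncated_poisson(rng, cfg.monthly_lambda, m), 12)
    perm = np.argsort(rng.random((m, 12)), axis=1) + 1
    mask = np.arange(12)[None, :] < k[:, None]
    months = perm[mask]
    rep = np.repeat(np.arange(m), k)
    n_rec = rep.size

    # true median unit price in current CNY
    irp = np.array([cfg.irp_usd[did] for did in drug_ids])
    year_arr = np.array(years)
    ppp = np.array([cfg.ppp_rate[min(int(yy), BASE_YEAR)] for yy in years])
    drift = np.array([(1.0 + cfg.inflation) ** max(0, int(yy) - BASE_YEAR) for yy in years])
    med = irp[d] * ppp[y] * lvl_arr[d, hreg, b, y] * drift[y]
    unit_price = med[rep] * np.exp(cfg.price_sigma * rng.standard_normal(n_rec))

    strength_mult = rng.choice([1.0, 2.0], size=n_rec, p=[0.7, 0.3])
    pack_size = rng.choice([10, 14, 20, 28, 30], size=n_rec)
    ref_val = np.array([dd.reference_strength_value for dd in cfg.drugs])
    ref_unit = np.array([dd.reference_strength_unit for dd in cfg.drugs], dtype=object)
    pack_price = unit_price * strength_mult * pack_size

    drug_names = np.array(drug_ids, dtype=object)
    brand_names = np.array(brands, dtype=object)
    forms = np.array([_DOSAGE_FORM.get(did, "tablet") for did in drug_ids], dtype=object)
    n_mfr = rng.integers(1, 7, size=n_rec)
    is_ib = brand_names[b[rep]] == "innovator_brand"
    manufacturer = np.where(
        is_ib,
        np.char.add(drug_names[d[rep]].astype(str), "-originator"),
        np.char.add(
            np.char.add(drug_names[d[rep]].astype(str), "-dom"),
            n_mfr.astype(str),
        ),
    )

    records = pd.DataFrame({
        "hospital_id": panel["hospital_id"].to_numpy()[h[rep]],
        "tier": panel["tier"].to_numpy()[h[rep]],
        "province": panel["province"].to_numpy()[h[rep]],
        "region": panel["region"].to_numpy()[h[rep]],
        "year": year_arr[y[rep]],
        "month": months,
        "drug_id": drug_names[d[rep]],
        "brand_status": brand_names[b[rep]],
        "dosage_form": forms[d[rep]],
        "strength_value": ref_val[d[rep]] * strength_mult,
        "strength_unit": ref_unit[d[rep]],
        "pack_size": pack_size,
        "pack_price": pack_price,
        "manufacturer": manufacturer,
    })

    price = cfg.price_level.copy()
    price["true_mpr"] = price["level"]
    ppp_map = {yy: cfg.ppp_rate[min(int(yy), BASE_YEAR)] for yy in years}
    drift_map = {yy: (1.0 + cfg.inflation) ** max(0, int(yy) - BASE_YEAR) for yy in years}
    price["true_median_unit_price"] = (
        price["drug_id"].map(cfg.irp_usd)
        * price["year"].map(ppp_map)
        * price["level"]
        * price["year"].map(drift_map)
    )
    truth = GroundTruth(
        stocking=cfg.stocking_prob.copy(),
        price=price,
        income=dict(cfg.income_params),
        region_hospitals=panel["region"].value_counts().to_dict(),
        inflation=cfg.inflation,
    )
    return records, panel, truth


def generate_income_tables(
    cfg: SimulationConfig,
) -> tuple[list[IncomeGroupTable], dict[tuple[int, str], tuple[float, float]]]:
    """Grouped income tables per year x sector with analytic quintile means.

    Group means are exact lognormal conditional means between quantile cut
    points (no sampling), so distribution-fit recovery tests carry no
    Monte-Carlo noise.
    """
    tables = []
    shares = np.full(cfg.income_groups, 1.0 / cfg.income_groups)
    for (year, sector), (mu, sigma) in sorted(cfg.income_params.items()):
        means = lognormal_group_means(mu, sigma, shares)
        tables.append(IncomeGroupTable(
            year=year, sector=sector,
            shares=tuple(shares), means=tuple(float(m) for m in means),
        ))
    return tables, dict(cfg.income_params)


def generate_reference_basis(cfg: SimulationConfig) -> ReferenceBasis:
    """Reference basis consistent with the simulated inflation:
    DF(y) = (1 + inflation)^(2013 - y)."""
    irp_usd = {d: {yr: v for yr in (2011, 2012, 2013)} for d, v in cfg.irp_usd.items()}
    discount = {
        yr: (1.0 + cfg.inflation) ** (BASE_YEAR - yr) if yr > BASE_YEAR else 1.0
        for yr in sorted(set(YEARS) | set(cfg.years))
    }
    return ReferenceBasis(irp_usd=irp_usd, ppp_rate=dict(cfg.ppp_rate), discount=discount)


def write_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize a full synthetic study as CSV + truth.json in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, panel, truth = generate_panel(cfg)
    basis = generate_reference_basis(cfg)
    tables, income_truth = generate_income_tables(cfg)

    paths = {name: outdir / f"{name}.csv" for name in
             ("records", "panel", "drugs", "irp", "ppp", "df", "income")}
    write_records(records, paths["records"])
    panel.to_csv(paths["panel"], index=False)
    write_drug_definitions(cfg.drugs, paths["drugs"])
    pd.DataFrame([
        {"drug_id": d, "year": yr, "irp_usd_per_unit": v}
        for d, by in basis.irp_usd.items() for yr, v in sorted(by.items())
    ]).to_csv(paths["irp"], index=False)
    pd.DataFrame(
        [{"year": y, "rate": r} for y, r in sorted(basis.ppp_rate.items())]
    ).to_csv(paths["ppp"], index=False)
    pd.DataFrame(
        [{"year": y, "df": basis.discount_factor(y)} for y in cfg.years]
    ).to_csv(paths["df"], index=False)
    pd.DataFrame([
        {"year": t.year, "sector": t.sector, "group_index": i + 1,
         "population_share": s, "mean_income": m}
        for t in tables for i, (s, m) in enumerate(zip(t.shares, t.means))
    ]).to_csv(paths["income"], index=False)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps({
        "stocking": truth.stocking.to_dict(orient="records"),
        "price": truth.price.to_dict(orient="records"),
        "income": {f"{y}_{s}": [mu, sg] for (y, s), (mu, sg) in income_truth.items()},
        "region_hospitals": truth.region_hospitals,
        "inflation": truth.inflation,
    }, indent=1))
    paths["truth"] = truth_path
    return paths
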