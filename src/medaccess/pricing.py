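"""Median unit prices, reference-price conversion and median price ratios.

The median price ratio (MPR) of a medicine is its median local unit price
divided by the international reference price (IRP) per unit: an MPR of 2
means the local price is twice the reference price, and an MPR of one or
less indicates efficient procurement.

Reference prices exist for 2011-2013 (in USD) and are converted to CNY with
purchasing-power-parity rates.  Local prices from 2014-2016 are deflated to
the 2013 price level with discount factors DF(y) = (1+r)^(2013-y) and
compared against the 2013 reference price; 2011-2013 prices use the
same-year reference price.  Each price batch carries a ``basis`` flag so the
pipeline can assert that deflation is applied exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .summaries import basket_median, product_specific_delta

__all__ = [
    "ReferenceBasis",
    "load_reference_basis",
    "irp_to_cny",
    "deflate_price",
    "deflate_prices",
    "median_unit_price",
    "mpr",
    "median_mpr",
    "delta_mpr",
    "ib_generic_ratio",
    "mpr_table",
]

BASE_YEAR = 2013

median_mpr = basket_median
delta_mpr = product_specific_delta


@dataclass(frozen=True)
class ReferenceBasis:
    """Everything needed to put a local price and an IRP on one 2013-CNY scale.

    Parameters
    ----------
    irp_usd
        ``{drug_id: {year: IRP per reference unit, USD}}`` for 2011-2013.
    ppp_rate
        ``{year: CNY per international dollar}``.
    discount
        Either an explicit ``{year: DF to 2013}`` table or ``None``, in which
        case factors derive from the annual ``rate`` r as
        ``DF(y) = (1+r)^(2013-y)``; DF(2013) is exactly 1.
    rate
        Annual discount rate used when no explicit table is given.
    """

    irp_usd: dict[str, dict[int, float]]
    ppp_rate: dict[int, float]
    discount: dict[int, float] | None = None
    rate: float = 0.03

    def __post_init__(self) -> None:
        for drug, by_year in self.irp_usd.items():
            for year, v in by_year.items():
                if v <= 0:
                    raise ValueError(f"nonpositive IRP for {drug} in {year}")
        for year, v in self.ppp_rate.items():
            if v <= 0:
                raise ValueError(f"nonpositive PPP rate in {year}")
        if self.discount is not None and self.discount.get(BASE_YEAR, 1.0) != 1.0:
            raise ValueError("DF(2013) must be exactly 1")

    def discount_factor(self, year: int) -> float:
        if year <= BASE_YEAR:
            return 1.0
        if self.discount is not None:
            if year not in self.discount:
                raise ValueError(f"no discount factor for {year}")
            return self.discount[year]
        return (1.0 + self.rate) ** (BASE_YEAR - year)

    def irp_cny(self, drug_id: str, year: int) -> float:
        """Reference price in CNY per unit; years after 2013 use the 2013 IRP."""
        irp_year = min(year, BASE_YEAR)
        try:
            usd = self.irp_usd[drug_id][irp_year]
        except KeyError:
            raise ValueError(f"no IRP for {drug_id} in {irp_year}") from None
        return irp_to_cny(usd, irp_year, self)


def load_reference_basis(basis_dir: str | Path, rate: float = 0.03) -> ReferenceBasis:
    """Load irp.csv, ppp.csv and (optionally) df.csv from a directory."""
    basis_dir = Path(basis_dir)
    irp = pd.read_csv(basis_dir / "irp.csv")
    ppp = pd.read_csv(basis_dir / "ppp.csv")
    irp_usd: dict[str, dict[int, float]] = {}
    for row in irp.itertuples(index=False):
        irp_usd.setdefault(row.drug_id, {})[int(row.year)] = float(row.irp_usd_per_unit)
    ppp_rate = {int(r.year): float(r.rate) for r in ppp.itertuples(index=False)}
    discount = None
    df_path = basis_dir / "df.csv"
    if df_path.exists():
        dff = pd.read_csv(df_path)
        discount = {int(r.year): float(r.df) for r in dff.itertuples(index=False)}
    return ReferenceBasis(irp_usd=irp_usd, ppp_rate=ppp_rate, discount=discount, rate=rate)


def irp_to_cny(irp_usd: float, year: int, basis: ReferenceBasis) -> float:
    """Convert a USD reference price to CNY by that year's PPP rate."""
    if year not in basis.ppp_rate:
        raise ValueError(f"no PPP conversion rate for {year}")
    return irp_usd * basis.ppp_rate[year]


def deflate_price(price: float, year: int, basis: ReferenceBasis) -> float:
    """Deflate one price to the 2013 level; years <= 2013 pass unchanged."""
    if not 2011 <= year <= 2016:
        raise ValueError(f"year {year} outside the survey window")
    return price * basis.discount_factor(year)


def deflate_prices(unit_prices: pd.DataFrame, basis: ReferenceBasis) -> pd.DataFrame:
    """Deflate a unit-price batch to the 2013 basis, exactly once.

    Raises if the batch is already on the 2013 basis (double deflation is a
    pipeline error, caught by the ``basis`` flag).
    """
    if (unit_prices["basis"] == "2013").any():
        raise ValueError("price batch already deflated to the 2013 basis")
    out = unit_prices.copy()
    factors = out["year"].map(basis.discount_factor)
    out["price_per_unit"] = out["price_per_unit"] * factors
    out["basis"] = "2013"
    return out


def median_unit_price(
    unit_prices: pd.DataFrame, median_method: str = "hospitals"
) -> float:
    """Median unit price of one stratum.

    ``hospitals`` (default, facility-level convention): each hospital
    contributes the median of its own transactions, and the stratum value is
    the median of the hospital values.  ``transactions`` pools all lines.
    Even counts use the mean of the central pair.
    """
    if unit_prices.empty:
        raise ValueError("empty stratum")
    if median_method == "transactions":
        return float(np.median(unit_prices["price_per_unit"]))
    if median_method != "hospitals":
        raise ValueError(f"unknown median method {median_method!r}")
    per_hospital = unit_prices.groupby("hospital_id", sort=False)["price_per_unit"].median()
    return float(np.median(per_hospital.to_numpy()))


def mpr(median_price_2013basis: float, irp_cny: float) -> float:
    """Median price ratio: local median unit price over the reference price."""
    if median_price_2013basis <= 0 or irp_cny <= 0:
        raise ValueError("prices must be positive")
    return median_price_2013basis / irp_cny


def ib_generic_ratio(mpr_ib: float, mpr_g: float) -> float:
    """Ratio of the innovator-brand basket MPR to the generic basket MPR."""
    if mpr_ib <= 0 or mpr_g <= 0:
        raise ValueError("MPRs must be positive")
    return mpr_ib / mpr_g


def round_report(x: float, ndigits: int = 2) -> float:
    """Reporting-layer rounding (round half to even); internal math is full precision."""
    return float(np.round(x, ndigits))


def mpr_table(
    unit_prices: pd.DataFrame,
    basis: ReferenceBasis,
    basket: list[str],
    years: list[int] | None = None,
    regions: list[str | None] = (None, "eastern", "central", "western"),
    brand_statuses: list[str | None] = (None,),
    median_method: str = "hospitals",
) -> pd.DataFrame:
    """MPR per drug x stratum x year: deflate once, take two-level medians,
    divide by the CNY reference price.  Rows with no prices are omitted."""
    deflated = deflate_prices(unit_prices, basis)
    if years is None:
        years = sorted(deflated["year"].unique())
    rows = []
    for region in regions:
        sub = deflated if region in (None, "nationwide") else deflated[
            deflated["region"] == region
        ]
        for brand in brand_statuses:
            s = sub if brand in (None, "all") else sub[sub["brand_status"] == brand]
            for drug in basket:
                sd = s[s["drug_id"] == drug]
                for year in years:
                    sdy = sd[sd["year"] == year]
                    if sdy.empty:
                        continue
                    med = median_unit_price(sdy, median_method)
                    rows.append({
                        "drug_id": drug,
                        "brand_status": brand or "all",
                        "year": year,
                        "region": region or "nationwide",
                        "mpr": mpr(med, basis.irp_cny(drug, year)),
                        "median_unit_price_2013cny": med,
                        "n_prices": len(sdy),
                    })
    return pd.DataFrame(rows)


def summarize_mpr(table: pd.DataFrame) -> pd.DataFrame:
    """Basket median MPR with product-specific deltas per stratum-year."""
    out = []
    for (region, brand), grp in table.groupby(["region", "brand_status"], sort=False):
        years = sorted(grp["year"].unique())
        for i, year in enumerate(years):
            med = basket_median(grp.loc[grp["year"] == year, "mpr"])
            delta = None
            if i > 0:
                delta, _ = product_specific_delta(
                    grp.rename(columns={"mpr": "value"}), (years[i - 1], year)
                )
            out.append({
                "region": region, "brand_status": brand, "year": year,
                "median_mpr": med, "delta_mpr": delta,
            })
    return pd.DataFrame(out)
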