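"""Facility availability of medicines across the hospital panel.

Availability of a medicine in a stratum-year is the percentage of *panel*
hospitals (from an explicit roster, not inferred from the records) with at
least one procurement record of the medicine in that window.  Hospitals with
zero records still count in the denominator; otherwise attrition inflates
availability.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .summaries import basket_median, product_specific_delta

__all__ = [
    "AvailabilityCell",
    "product_availability",
    "median_availability",
    "delta_product_specific",
    "availability_table",
]

median_availability = basket_median
delta_product_specific = product_specific_delta


@dataclass(frozen=True)
class AvailabilityCell:
    drug_id: str
    brand_status: str       # "innovator_brand" | "generic" | "all"
    year: int
    region: str             # region name or "nationwide"
    tier: str               # tier name or "all"
    availability_pct: float
    n_hospitals: int        # stratum panel size, not the stocking count

    def __post_init__(self) -> None:
        if not 0.0 <= self.availability_pct <= 100.0:
            raise ValueError("availability must lie in [0, 100]")
        if self.n_hospitals <= 0:
            raise ValueError("empty stratum")


def _panel_subset(panel: pd.DataFrame, region: str | None, tier: str | None) -> pd.DataFrame:
    sub = panel
    if region is not None and region != "nationwide":
        sub = sub[sub["region"] == region]
    if tier is not None and tier != "all":
        sub = sub[sub["tier"] == tier]
    return sub


def product_availability(
    records: pd.DataFrame,
    panel: pd.DataFrame,
    drug_id: str,
    year: int,
    region: str | None = None,
    tier: str | None = None,
    brand_status: str | None = None,
) -> AvailabilityCell:
    """Availability of one medicine in one calendar-year window and stratum."""
    roster = _panel_subset(panel, region, tier)
    if roster.empty:
        raise ValueError(
            f"empty stratum: region={region or 'nationwide'}, tier={tier or 'all'}"
        )
    mask = (records["drug_id"] == drug_id) & (records["year"] == year)
    if brand_status is not None and brand_status != "all":
        mask &= records["brand_status"] == brand_status
    stocking = records.loc[mask, "hospital_id"].unique()
    n_stock = roster["hospital_id"].isin(stocking).sum()
    return AvailabilityCell(
        drug_id=drug_id,
        brand_status=brand_status or "all",
        year=year,
        region=region or "nationwide",
        tier=tier or "all",
        availability_pct=100.0 * n_stock / len(roster),
        n_hospitals=len(roster),
    )


def availability_table(
    records: pd.DataFrame,
    panel: pd.DataFrame,
    basket: list[str],
    years: list[int] | None = None,
    regions: list[str | None] = (None, "eastern", "central", "western"),
    brand_statuses: list[str | None] = (None,),
    tier: str | None = None,
) -> pd.DataFrame:
    """Full stratified availability grid, one row per drug x stratum x year.

    Vectorized equivalent of calling :func:`product_availability` over the
    grid; ordering is deterministic (basket order, then year, region, brand).
    """
    if years is None:
        years = sorted(records["year"].unique())
    known = set(panel["region"].unique()) | {None, "nationwide"}
    bad = [r for r in regions if r not in known]
    if bad:
        raise ValueError(f"unknown stratum key(s): {bad}")

    rows = []
    for region in regions:
        roster = _panel_subset(panel, region, tier)
        if roster.empty:
            raise ValueError(f"empty stratum: region={region}")
        n_panel = len(roster)
        in_roster = records["hospital_id"].isin(set(roster["hospital_id"]))
        sub = records.loc[in_roster & records["drug_id"].isin(basket)]
        for brand in brand_statuses:
            s = sub if brand in (None, "all") else sub[sub["brand_status"] == brand]
            counts = (
                s.groupby(["drug_id", "year"], sort=False)["hospital_id"]
                .nunique()
            )
            for drug in basket:
                for year in years:
                    n_stock = int(counts.get((drug, year), 0))
                    rows.append({
                        "drug_id": drug,
                        "brand_status": brand or "all",
                        "year": year,
                        "region": region or "nationwide",
                        "tier": tier or "all",
                        "availability_pct": 100.0 * n_stock / n_panel,
                        "n_hospitals": n_panel,
                    })
    return pd.DataFrame(rows)


def summarize_availability(table: pd.DataFrame) -> pd.DataFrame:
    """Basket medians with product-specific deltas per stratum-year.

    Mirrors the survey-style layout: one row per (region, brand, year) with
    the basket median availability and the median over drugs of each drug's
    change from the previous year.
    """
    out = []
    for (region, brand), grp in table.groupby(["region", "brand_status"], sort=False):
        years = sorted(grp["year"].unique())
        for i, year in enumerate(years):
            med = basket_median(grp.loc[grp["year"] == year, "availability_pct"])
            delta = None
            if i > 0:
                delta, _ = product_specific_delta(
                    grp.rename(columns={"availability_pct": "value"}),
                    (years[i - 1], year),
                )
            out.append({
                "region": region, "brand_status": brand, "year": year,
                "median_availability_pct": med, "delta_availability": delta,
            })
    return pd.DataFrame(out)
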