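"""Record schemas, delimited-file IO and smallest-unit price normalization.

The procurement panel is held as a tidy :class:`pandas.DataFrame` with one row
per hospital-month purchase line.  Raw lines are validated against the schema
below; rows violating an invariant are diverted to a rejects report (with the
source line number and a reason) rather than aborting the run, because
observational procurement data is dirty.

All strengths of one chemical are made commensurable by normalizing the pack
price to a price per *reference unit*: the price per mg (or per activity unit)
of active moiety, rescaled to a single declared reference strength per drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PROVINCE_REGION",
    "RECORD_COLUMNS",
    "DRUG_COLUMNS",
    "DrugDefinition",
    "UnitConversionError",
    "convert_amount",
    "read_records",
    "write_records",
    "read_drug_definitions",
    "write_drug_definitions",
    "smallest_unit_price",
    "unit_price_table",
]

#: Standard Chinese statistical grouping of the 28 surveyed provinces
#: (Qinghai, Tibet and Hainan are not in the panel).  Override by passing an
#: explicit mapping to :func:`read_records`.
PROVINCE_REGION: dict[str, str] = {
    # eastern (10)
    "Beijing": "eastern", "Tianjin": "eastern", "Hebei": "eastern",
    "Liaoning": "eastern", "Shanghai": "eastern", "Jiangsu": "eastern",
    "Zhejiang": "eastern", "Fujian": "eastern", "Shandong": "eastern",
    "Guangdong": "eastern",
    # central (8)
    "Shanxi": "central", "Jilin": "central", "Heilongjiang": "central",
    "Anhui": "central", "Jiangxi": "central", "Henan": "central",
    "Hubei": "central", "Hunan": "central",
    # western (10)
    "Inner Mongolia": "western", "Guangxi": "western", "Chongqing": "western",
    "Sichuan": "western", "Guizhou": "western", "Yunnan": "western",
    "Shaanxi": "western", "Gansu": "western", "Ningxia": "western",
    "Xinjiang": "western",
}

REGIONS = ("eastern", "central", "western")
TIERS = ("secondary", "tertiary")
BRAND_STATUSES = ("innovator_brand", "generic")

RECORD_COLUMNS = [
    "hospital_id", "tier", "province", "region", "year", "month",
    "drug_id", "brand_status", "dosage_form", "strength_value",
    "strength_unit", "pack_size", "pack_price", "manufacturer",
]

DRUG_COLUMNS = [
    "drug_id", "therapeutic_class", "disorder_type", "on_neml",
    "reference_strength_value", "reference_strength_unit",
    "ddd_value", "ddd_unit",
]

# mass units expressed in mg of active moiety; activity units (IU, U) only
# convert to themselves
_MASS_MG = {"g": 1000.0, "mg": 1.0, "ug": 1e-3, "mcg": 1e-3, "ng": 1e-6}


class UnitConversionError(ValueError):
    """Raised when two strength units cannot be put on a common scale."""


def convert_amount(value: float, unit: str, to_unit: str) -> float:
    """Convert an amount of active moiety between strength units.

    Mass units (g, mg, ug/mcg, ng) interconvert; activity units (e.g. IU)
    convert only to the identical unit.
    """
    u, v = unit.strip(), to_unit.strip()
    if u.lower() == v.lower():
        return float(value)
    fu, fv = _MASS_MG.get(u.lower()), _MASS_MG.get(v.lower())
    if fu is None or fv is None:
        raise UnitConversionError(
            f"cannot convert between units {unit!r} and {to_unit!r}"
        )
    return float(value) * fu / fv


@dataclass(frozen=True)
class DrugDefinition:
    """One surveyed medicine: chemical identity and dosing conventions.

    ``reference_strength_value``/``unit`` declare the smallest unit all
    strengths of this chemical are rescaled to; ``ddd_value``/``unit`` is the
    defined daily dose (amount of active moiety per treatment day).
    """

    drug_id: str
    therapeutic_class: str
    disorder_type: str          # "acute" | "chronic"
    on_neml: bool
    reference_strength_value: float
    reference_strength_unit: str
    ddd_value: float
    ddd_unit: str

    def __post_init__(self) -> None:
        if self.reference_strength_value <= 0:
            raise ValueError(f"{self.drug_id}: reference strength must be > 0")
        if self.ddd_value <= 0:
            raise ValueError(f"{self.drug_id}: DDD must be > 0")
        if self.disorder_type not in ("acute", "chronic"):
            raise ValueError(f"{self.drug_id}: bad disorder_type {self.disorder_type!r}")
        # must not raise
        convert_amount(self.ddd_value, self.ddd_unit, self.reference_strength_unit)

    @property
    def units_per_day(self) -> float:
        """Reference units consumed per treatment day (DDD / reference strength)."""
        ddd = convert_amount(self.ddd_value, self.ddd_unit, self.reference_strength_unit)
        return ddd / self.reference_strength_value


def _validation_masks(df: pd.DataFrame) -> list[tuple[pd.Series, str]]:
    """(bad-row mask, reason) pairs for every record invariant."""
    checks = [
        (~df["tier"].isin(TIERS), "unknown tier"),
        (df["year"].isna() | ~df["year"].between(2011, 2016), "year out of range"),
        (df["month"].isna() | ~df["month"].between(1, 12), "month out of range"),
        (~df["brand_status"].isin(BRAND_STATUSES), "unknown brand status"),
        (df["strength_value"].isna() | (df["strength_value"] <= 0), "nonpositive strength"),
        (df["pack_size"].isna() | (df["pack_size"] < 1), "pack size below one"),
        (df["pack_price"].isna() | (df["pack_price"] <= 0), "nonpositive price"),
        (df["drug_id"].isna() | (df["drug_id"].astype(str).str.len() == 0), "missing drug id"),
    ]
    return checks


def read_records(
    path: str | Path,
    province_region: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a procurement-record CSV, enforcing the schema invariants.

    Returns ``(records, rejects)``.  ``records`` holds the rows that pass all
    invariants, typed; ``rejects`` carries the offending raw rows with a
    ``line`` (1-based, counting the header) and ``reason`` column.  Malformed
    rows never abort the run.  An unknown province, however, is a
    configuration error and raises ``ValueError`` naming the province.
    """
    province_region = dict(province_region or PROVINCE_REGION)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns and c != "region"]
    if missing:
        raise ValueError(f"header missing required columns: {missing}")

    df = raw.copy()
    for col in ("year", "month", "pack_size"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in ("strength_value", "pack_price"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    unknown = sorted(set(df["province"]) - set(province_region))
    if unknown:
        raise ValueError(f"unknown province(s): {', '.join(unknown)}")
    mapped = df["province"].map(province_region)
    if "region" not in df.columns or (df["region"] == "").all():
        df["region"] = mapped
    else:
        df["region"] = df["region"].where(df["region"] != "", mapped)
    bad_region = df["region"] != mapped
    if bad_region.any():
        prov = df.loc[bad_region, "province"].iloc[0]
        raise ValueError(f"region column inconsistent with province map (e.g. {prov})")

    reason = pd.Series("", index=df.index)
    for mask, why in _validation_masks(df):
        reason = reason.mask(mask & (reason == ""), why)
    bad = reason != ""
    rejects = raw.loc[bad].copy()
    rejects.insert(0, "line", rejects.index + 2)  # +1 header, +1 1-based
    rejects["reason"] = reason[bad]
    good = df.loc[~bad, RECORD_COLUMNS].copy()
    good["year"] = good["year"].astype(int)
    good["month"] = good["month"].astype(int)
    good["pack_size"] = good["pack_size"].astype(int)
    return good.reset_index(drop=True), rejects.reset_index(drop=True)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as UTF-8 CSV with the documented column order."""
    records.loc[:, RECORD_COLUMNS].to_csv(path, index=False)


def read_drug_definitions(path: str | Path) -> dict[str, DrugDefinition]:
    """Read the drug-definition table into ``{drug_id: DrugDefinition}``."""
    df = pd.read_csv(path)
    missing = [c for c in DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"drug table missing columns: {missing}")
    out: dict[str, DrugDefinition] = {}
    for row in df.itertuples(index=False):
        d = DrugDefinition(
            drug_id=row.drug_id,
            therapeutic_class=row.therapeutic_class,
            disorder_type=row.disorder_type,
            on_neml=bool(row.on_neml),
            reference_strength_value=float(row.reference_strength_value),
            reference_strength_unit=str(row.reference_strength_unit),
            ddd_value=float(row.ddd_value),
            ddd_unit=str(row.ddd_unit),
        )
        out[d.drug_id] = d
    return out


def write_drug_definitions(defs: Iterable[DrugDefinition], path: str | Path) -> None:
    pd.DataFrame([vars(d) for d in defs])[DRUG_COLUMNS].to_csv(path, index=False)


def smallest_unit_price(record: Mapping, definition: DrugDefinition) -> float:
    """Price per reference-strength unit of one purchase line, in CNY.

    ``(pack_price / pack_size)`` is the price of one smallest unit at the
    line's strength; dividing by the line's strength (converted into the
    drug's reference unit) gives a per-mg price, and rescaling by the
    reference strength gives the price per reference unit — so all strengths
    of one chemical pool comparably.
    """
    if record["drug_id"] != definition.drug_id:
        raise ValueError(
            f"record drug {record['drug_id']!r} does not match "
            f"definition {definition.drug_id!r}"
        )
    strength_ref = convert_amount(
        record["strength_value"], record["strength_unit"],
        definition.reference_strength_unit,
    )
    if strength_ref <= 0 or record["pack_size"] < 1 or record["pack_price"] <= 0:
        raise ValueError("record violates positivity invariants")
    per_unit = record["pack_price"] / record["pack_size"]
    return per_unit * definition.reference_strength_value / strength_ref


def unit_price_table(
    records: pd.DataFrame, definitions: Mapping[str, DrugDefinition]
) -> pd.DataFrame:
    """Vectorized smallest-unit normalization of a whole record table.

    Returns one row per purchase line with ``price_per_unit`` (CNY per
    reference-strength unit) and the stratification columns, plus a ``basis``
    column marking prices as nominal (not yet deflated).
    """
    unknown = sorted(set(records["drug_id"]) - set(definitions))
    if unknown:
        raise ValueError(f"records reference undefined drugs: {unknown}")
    ref_val = records["drug_id"].map(
        {k: d.reference_strength_value for k, d in definitions.items()}
    )
    ref_unit = records["drug_id"].map(
        {k: d.reference_strength_unit for k, d in definitions.items()}
    )
    pairs = pd.DataFrame({"u": records["strength_unit"].to_numpy(), "v": ref_unit.to_numpy()})
    uniq = pairs.drop_duplicates()
    factor_map = {
        (u, v): convert_amount(1.0, u, v) for u, v in zip(uniq["u"], uniq["v"])
    }
    factor = np.array([factor_map[(u, v)] for u, v in zip(pairs["u"], pairs["v"])])
    strength_ref = records["strength_value"].to_numpy() * factor
    price = (
        records["pack_price"].to_numpy() / records["pack_size"].to_numpy()
        * ref_val.to_numpy() / strength_ref
    )
    out = records.loc[
        :, ["drug_id", "brand_status", "hospital_id", "tier", "province",
            "region", "year"]
    ].copy()
    out["price_per_unit"] = price
    out["basis"] = "nominal"
    return out
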