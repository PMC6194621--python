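"""Shared fixtures: tiny drug definitions and scaled-down synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from medaccess import DrugDefinition, default_config
from medaccess.simulate import SimulationConfig


def shrink_config(
    cfg: SimulationConfig,
    drug_ids: list[str] | None = None,
    n_secondary: int = 40,
    n_tertiary: int = 60,
    years: tuple[int, ...] | None = None,
) -> SimulationConfig:
    """Cut a config down to a fast test-sized study (fewer drugs/hospitals)."""
    cfg.n_secondary = n_secondary
    cfg.n_tertiary = n_tertiary
    if drug_ids is not None:
        cfg.drugs = [d for d in cfg.drugs if d.drug_id in drug_ids]
        keep = cfg.stocking_prob["drug_id"].isin(drug_ids)
        cfg.stocking_prob = cfg.stocking_prob[keep].reset_index(drop=True)
        keep = cfg.price_level["drug_id"].isin(drug_ids)
        cfg.price_level = cfg.price_level[keep].reset_index(drop=True)
        cfg.irp_usd = {k: v for k, v in cfg.irp_usd.items() if k in drug_ids}
    if years is not None:
        cfg.years = years
        cfg.stocking_prob = cfg.stocking_prob[
            cfg.stocking_prob["year"].isin(years)
        ].reset_index(drop=True)
        cfg.price_level = cfg.price_level[
            cfg.price_level["year"].isin(years)
        ].reset_index(drop=True)
    return cfg


def flat_config(
    seed: int,
    p: float,
    level: float,
    n_secondary: int = 50,
    n_tertiary: int = 50,
    years: tuple[int, ...] = (2013,),
    price_sigma: float = 0.2,
    drug_id: str = "metformin",
) -> SimulationConfig:
    """One-drug config with a single stocking probability and price level
    everywhere — the simplest panel with exactly known truth."""
    cfg = shrink_config(default_config(seed), [drug_id], n_secondary, n_tertiary, years)
    cfg.stocking_prob = cfg.stocking_prob.assign(p=p)
    cfg.price_level = cfg.price_level.assign(level=level)
    cfg.price_sigma = price_sigma
    return cfg


@pytest.fixture
def amoxicillin() -> DrugDefinition:
    return DrugDefinition(
        drug_id="amoxicillin", therapeutic_class="antibiotic",
        disorder_type="acute", on_neml=True,
        reference_strength_value=250.0, reference_strength_unit="mg",
        ddd_value=1500.0, ddd_unit="mg",
    )


@pytest.fixture
def tiny_panel() -> pd.DataFrame:
    """Ten hospitals across the three regions."""
    provinces = ["Beijing", "Jiangsu", "Shandong", "Henan", "Hubei", "Hunan",
                 "Sichuan", "Yunnan", "Gansu", "Shaanxi"]
    regions = ["eastern", "eastern", "eastern", "central", "central", "central",
               "western", "western", "western", "western"]
    return pd.DataFrame({
        "hospital_id": [f"H{i:04d}" for i in range(1, 11)],
        "tier": ["secondary"] * 5 + ["tertiary"] * 5,
        "province": provinces,
        "region": regions,
    })


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Procurement records from sparse dicts, with sensible defaults."""
    base = {
        "hospital_id": "H0001", "tier": "secondary", "province": "Beijing",
        "region": "eastern", "year": 2013, "month": 1,
        "drug_id": "amoxicillin", "brand_status": "generic",
        "dosage_form": "tablet", "strength_value": 250.0,
        "strength_unit": "mg", "pack_size": 10, "pack_price": 10.0,
        "manufacturer": "m1",
    }
    return pd.DataFrame([{**base, **r} for r in rows])
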