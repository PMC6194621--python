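"""Generate the synthetic procurement study that drives analyses 02-04.

Builds the default study conditions (seed 42): 396 secondary + 763 tertiary
hospitals in 28 provinces, 30 surveyed medicines in innovator-brand and
generic versions, monthly purchase lines 2011-2016, a PPP/discount reference
basis, and urban/rural grouped income tables 2011-2014.  The small input
tables and the analytic ground truth go to results/data/; the purchase-line
table itself (~1M rows) is regenerated deterministically by each later
driver rather than stored.
"""

from pathlib import Path

import pandas as pd

from medaccess import default_config, generate_income_tables, generate_panel
from medaccess.simulate import write_dataset

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    cfg = default_config(SEED)
    records, panel, truth = generate_panel(cfg)
    print(f"panel: {len(panel)} hospitals "
          f"({(panel.tier == 'secondary').sum()} secondary, "
          f"{(panel.tier == 'tertiary').sum()} tertiary) in "
          f"{panel.province.nunique()} provinces")
    print(f"records: {len(records):,} purchase lines, "
          f"{records.drug_id.nunique()} medicines, years "
          f"{records.year.min()}-{records.year.max()}")

    paths = write_dataset(cfg, OUT)
    # the full record table is bulky and fully reproducible from the seed
    paths["records"].unlink()
    tables, _ = generate_income_tables(cfg)
    print(f"income tables: {len(tables)} year x sector grids "
          f"(analytic lognormal quintiles)")
    print(f"wrote inputs + truth.json to {OUT}")


if __name__ == "__main__":
    main()
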