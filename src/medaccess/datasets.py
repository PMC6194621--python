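"""Small published reference tables used as inputs by the analysis drivers.

These are observed summary statistics from a national 2011-2016 survey of
essential-medicines access in Chinese secondary and tertiary hospitals; they
serve as *inputs* to arithmetic the package performs (e.g. the ratio of the
innovator-brand basket MPR to the generic basket MPR), never as fitted
targets.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["brand_generic_mpr_medians"]

# year -> (median MPR of innovator-brand basket, median MPR of generic basket),
# n = 16 medicines per basket
_MPR_BY_BRAND = {
    2011: (29.51, 8.06),
    2012: (33.07, 8.28),
    2013: (37.20, 7.18),
    2014: (36.57, 7.05),
    2015: (28.07, 5.77),
    2016: (34.76, 5.50),
}


def brand_generic_mpr_medians() -> pd.DataFrame:
    """Observed annual median MPRs by brand status (innovator vs generic)."""
    return pd.DataFrame(
        [
            {"year": y, "mpr_innovator": ib, "mpr_generic": g}
            for y, (ib, g) in sorted(_MPR_BY_BRAND.items())
        ]
    )
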