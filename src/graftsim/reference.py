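"""Packaged reference tables: published chamber costs and labor comparison.

These ship with the package as plain CSV and serve as fixed inputs for
derived quantities (cost identities, percentage reductions) that do not
depend on the unpublished scenario magnitudes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .labor import reduction_report


def load_reference_chamber_table() -> pd.DataFrame:
    with resources.files("graftsim.data").joinpath("chamber_costs_reference.csv").open() as fh:
        return pd.read_csv(fh).set_index("crop")


def load_reference_labor_table() -> pd.DataFrame:
    with resources.files("graftsim.data").joinpath("labor_comparison_reference.csv").open() as fh:
        return pd.read_csv(fh)


def reference_reductions() -> pd.DataFrame:
    """Percent reductions (with vs without storage) per crop x scenario row.

    Computed from the packaged labor-comparison table via the same
    ``reduction_report`` rule used for simulated ledgers.
    """
    df = load_reference_labor_table()
    rows = []
    for (crop, scen), grp in df.groupby(["crop", "scenario"]):
        w = grp[grp.storage == "yes"].iloc[0]
        wo = grp[grp.storage == "no"].iloc[0]
        red = reduction_report(
            {
                "max_workers": w.max_workers,
                "peak_cost": w.peak_cost_usd_per_plant,
                "overall_cost": w.overall_cost_usd_per_plant,
            },
            {
                "max_workers": wo.max_workers,
                "peak_cost": wo.peak_cost_usd_per_plant,
                "overall_cost": wo.overall_cost_usd_per_plant,
            },
        )
        rows.append({"crop": crop, "scenario": scen, **red})
    return pd.DataFrame(rows)
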