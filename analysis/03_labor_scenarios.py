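#!/usr/bin/env python
"""Six production scenarios: with- vs without-storage labor comparison.

Two crops (tomato: 4 storage weeks, watermelon: 2) crossed with three
production-peak patterns (single-week peak, multi-week consistent peak,
12-week descending peak).  Each run optimizes the grafting schedule,
simulates five stochastic replicates per arm, and compares peak labor
and per-plant costs.  Writes results/labor_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from graftsim import RunConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 20260929
PATTERNS = {
    "single_peak": dict(pattern="single_peak", peak_start=12, peak_len=1),
    "multi_week_consistent": dict(pattern="multi_week_consistent", peak_start=10, peak_len=4),
    "multi_week_descending": dict(pattern="multi_week_descending", peak_start=8, peak_len=12),
}

rows = []
for crop in ("tomato", "watermelon"):
    for name, kw in PATTERNS.items():
        cfg = RunConfig(crop=crop, baseline=60, peak=600, horizon=24, reps=5, seed=SEED, **kw)
        rep = run_pipeline(cfg)
        t = rep.table
        rows.append(
            {
                "crop": crop,
                "pattern": name,
                "max_workers_with": t.loc["max_workers", "with_mean"],
                "max_workers_without": t.loc["max_workers", "without_mean"],
                "peak_labor_reduction_pct": t.loc["max_workers", "reduction_pct"],
                "peak_cost_with_usd_plant": round(
                    t.loc["peak_week_cost_per_plant", "with_mean"], 3
                ),
                "peak_cost_without_usd_plant": round(
                    t.loc["peak_week_cost_per_plant", "without_mean"], 3
                ),
                "peak_cost_reduction_pct": t.loc["peak_week_cost_per_plant", "reduction_pct"],
                "overall_cost_reduction_pct": t.loc["overall_cost_per_plant", "reduction_pct"],
                "peak_cost_p_value": round(t.loc["peak_week_cost_per_plant", "p_value"], 4),
                "peak_storage_trays": rep.storage_peak_trays,
            }
        )
        print(
            f"{crop:10s} {name:22s} peak workers {rows[-1]['max_workers_without']:.0f}"
            f" -> {rows[-1]['max_workers_with']:.0f}"
            f" ({rows[-1]['peak_labor_reduction_pct']:.0f}% lower);"
            f" peak-week cost ${rows[-1]['peak_cost_without_usd_plant']:.3f}"
            f" -> ${rows[-1]['peak_cost_with_usd_plant']:.3f}/plant"
        )

df = pd.DataFrame(rows)
df.to_csv(OUT / "labor_comparison.csv", index=False)
print(
    f"\nPeak-labor reductions span {df.peak_labor_reduction_pct.min():.0f}-"
    f"{df.peak_labor_reduction_pct.max():.0f}% across the six scenarios; "
    "watermelon benefits less because its 2-week storability limits how far "
    "grafting can be shifted ahead of the peak."
)
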