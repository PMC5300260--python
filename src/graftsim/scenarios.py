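"""Weekly shipment-demand scenarios for a grafting nursery.

A scenario is the demand side of the planning problem: how many seedling
trays must ship in each week of the planning horizon.  Three stylized peak
patterns cover the situations a seasonal nursery faces:

``single_peak``
    a flat baseline with one extreme shipping week (a single large field
    planting date),
``multi_week_consistent``
    a sustained plateau of several identical peak weeks,
``multi_week_descending``
    a peak that decays linearly back to the baseline over several weeks
    (staggered planting windows that tail off).

Weeks are 1-based and contiguous; trays are non-negative integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PATTERNS = ("single_peak", "multi_week_consistent", "multi_week_descending", "custom")


class ScenarioError(ValueError):
    """Invalid scenario construction or file contents."""


@dataclass(frozen=True)
class ShipmentScenario:
    """Weekly tray demand for one crop over a contiguous 1-based horizon."""

    crop: str
    demand: tuple[int, ...]
    pattern: str = "custom"

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ScenarioError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if len(self.demand) < 1:
            raise ScenarioError("horizon must cover at least 1 week")
        demand = tuple(int(d) for d in self.demand)
        if any(d < 0 for d in demand):
            raise ScenarioError("demand must be non-negative")
        if not any(d > 0 for d in demand):
            raise ScenarioError("at least one week must have positive demand")
        object.__setattr__(self, "demand", demand)

    @property
    def horizon_weeks(self) -> int:
        return len(self.demand)

    @property
    def weeks(self) -> range:
        """1-based week indices."""
        return range(1, self.horizon_weeks + 1)

    @property
    def total_trays(self) -> int:
        return sum(self.demand)


def make_scenario(
    pattern: str,
    baseline: int,
    peak: int,
    peak_start: int,
    peak_len: int,
    horizon: int,
    crop: str = "tomato",
    seed: int | None = None,
    noise_frac: float = 0.0,
) -> ShipmentScenario:
    """Construct a scenario with one of the stylized production-peak shapes.

    ``single_peak`` forces ``peak_len`` to 1.  ``multi_week_descending``
    interpolates linearly from ``peak`` down to ``baseline`` across the
    peak window, rounding to whole trays.  Multiplicative demand noise
    (``noise_frac`` > 0) is off by default: scenarios are fixed planning
    inputs, and the stochasticity belongs to the production simulator.
    """
    if pattern not in PATTERNS or pattern == "custom":
        raise ScenarioError(f"unknown generated pattern {pattern!r}")
    if horizon < 1:
        raise ScenarioError("horizon must be >= 1 week")
    if not (peak >= baseline >= 0):
        raise ScenarioError("need peak >= baseline >= 0")
    if pattern == "single_peak":
        peak_len = 1
    if peak_start < 1 or peak_start + peak_len - 1 > horizon:
        raise ScenarioError("peak window must lie inside the horizon")

    demand = np.full(horizon, baseline, dtype=float)
    window = slice(peak_start - 1, peak_start - 1 + peak_len)
    if pattern in ("single_peak", "multi_week_consistent"):
        demand[window] = peak
    else:  # multi_week_descending
        if peak_len == 1:
            demand[window] = peak
        else:
            demand[window] = np.linspace(peak, baseline, peak_len)

    if noise_frac > 0.0:
        rng = np.random.default_rng(seed)
        demand = demand * np.clip(rng.normal(1.0, noise_frac, horizon), 0.0, None)

    return ShipmentScenario(
        crop=crop, demand=tuple(int(round(d)) for d in demand), pattern=pattern
    )


def _validate_week_table(weeks: Sequence[int], trays: Sequence[int]) -> tuple[int, ...]:
    weeks = [int(w) for w in weeks]
    if len(set(weeks)) != len(weeks):
        dupes = sorted({w for w in weeks if weeks.count(w) > 1})
        raise ScenarioError(f"duplicate week indices: {dupes}")
    expected = list(range(1, max(weeks) + 1)) if weeks else []
    missing = sorted(set(expected) - set(weeks))
    if missing or (weeks and min(weeks) != 1):
        raise ScenarioError(f"weeks must be contiguous from 1; missing week(s) {missing or [1]}")
    order = np.argsort(weeks)
    out = []
    for i in order:
        t = trays[i]
        if float(t) != int(t) or int(t) < 0:
            raise ScenarioError(f"week {weeks[i]}: trays must be a non-negative integer, got {t}")
        out.append(int(t))
    return tuple(out)


def read_scenario(path: str | Path, crop: str | None = None) -> ShipmentScenario:
    """Read a scenario from CSV (columns ``week,trays``) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        demand = _validate_week_table(payload["weeks"], payload["trays"])
        return ShipmentScenario(
            crop=crop or payload.get("crop", "unknown"),
            demand=demand,
            pattern=payload.get("pattern", "custom"),
        )
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "week" not in cols or "trays" not in cols:
        raise ScenarioError(f"{path}: expected columns week,trays; found {list(df.columns)}")
    demand = _validate_week_table(df[cols["week"]].tolist(), df[cols["trays"]].tolist())
    return ShipmentScenario(crop=crop or "unknown", demand=demand, pattern="custom")


def write_scenario(scenario: ShipmentScenario, path: str | Path) -> Path:
    """Write a scenario to CSV or JSON (chosen by file suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "crop": scenario.crop,
            "pattern": scenario.pattern,
            "weeks": list(scenario.weeks),
            "trays": list(scenario.demand),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        pd.DataFrame({"week": list(scenario.weeks), "trays": list(scenario.demand)}).to_csv(
            path, index=False
        )
    return path
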