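"""Scenario comparison: opportunity/productivity costs, 18-year
cumulative series, national scale-up, and summary reports.

Opportunity cost is the farmer's financial penalty for foregoing
business-as-usual and switching to mitigation (BAU minus MIT mean
annual gross profit); productivity cost is the analogous wheat-yield
difference. Negative values mean mitigation outperforms BAU.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .strategies import DR_LABELS, REGIONS

__all__ = [
    "opportunity_cost",
    "productivity_cost",
    "cumulative_costs",
    "CountyAreaTable",
    "scale_up",
    "percent_of_reference",
    "relative_reduction",
    "compare_scenarios",
]


def opportunity_cost(gp_bau, gp_mit):
    """Mean annual gross profit BAU minus MIT (GBP/ha/yr)."""
    return np.subtract(gp_bau, gp_mit)


def productivity_cost(y_bau, y_mit):
    """Mean annual wheat yield BAU minus MIT (t/ha/yr)."""
    return np.subtract(y_bau, y_mit)


def cumulative_costs(reference: Sequence[float], sequence: Sequence[float]) -> np.ndarray:
    """Running sum of per-year (reference - sequence) differences.

    Used for the 18-year switching analysis with continuous BAU (BBB)
    as the reference; apply once to gross profit and once to wheat
    yield series.
    """
    ref = np.asarray(reference, dtype=float)
    seq = np.asarray(sequence, dtype=float)
    if ref.shape != seq.shape:
        raise ValueError("reference and sequence series must have equal length")
    return np.cumsum(ref - seq)


def percent_of_reference(value: float, reference: float, ndigits: int | None = 1) -> float:
    """Express ``value`` as a percentage of ``reference``.

    Rounding happens only at this reporting layer; pass ``ndigits=None``
    for the raw percentage.
    """
    if reference == 0:
        raise ZeroDivisionError("reference must be non-zero")
    pct = 100.0 * value / reference
    return pct if ndigits is None else round(pct, ndigits)


def relative_reduction(baseline: float, treatment: float, ndigits: int | None = 1) -> float:
    """100 * (baseline - treatment) / baseline."""
    if baseline == 0:
        raise ZeroDivisionError("baseline must be non-zero")
    pct = 100.0 * (baseline - treatment) / baseline
    return pct if ndigits is None else round(pct, ndigits)


@dataclass
class CountyAreaTable:
    """County cereal areas with within-county DR-category shares.

    Scale-up assumes the density-resistance mix within a county matches
    the mix observed among that county's surveyed fields.
    """

    frame: pd.DataFrame  # columns: county, region, cereal_area_ha, share_<DR>

    SHARE_COLUMNS = tuple(f"share_{lab}" for lab in DR_LABELS)

    def __post_init__(self) -> None:
        required = {"county", "region", "cereal_area_ha", *self.SHARE_COLUMNS}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"county table missing columns: {sorted(missing)}")
        bad_region = set(self.frame["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown regions in county table: {sorted(bad_region)}")
        if (self.frame["cereal_area_ha"] < 0).any():
            raise ValueError("cereal areas must be >= 0")
        share_sums = self.frame[list(self.SHARE_COLUMNS)].sum(axis=1)
        off = self.frame.loc[(share_sums - 1.0).abs() > 1e-6, "county"]
        if len(off):
            raise ValueError(
                f"category shares must sum to 1 per county; violated by {list(off)}"
            )

    @property
    def counties(self) -> list[str]:
        return list(self.frame["county"])

    def region_of(self, county: str) -> str:
        sub = self.frame[self.frame["county"] == county]
        if sub.empty:
            raise KeyError(f"county {county!r} not in the county->region table")
        return str(sub["region"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountyAreaTable":
        return cls(pd.read_csv(path))

    @classmethod
    def load_default(cls) -> "CountyAreaTable":
        with resources.as_file(
            resources.files("weedrot.data") / "county_areas.csv"
        ) as p:
            return cls.from_csv(p)


def scale_up(
    per_ha_value: Mapping[tuple[str, str], float] | Mapping[str, float],
    areas: CountyAreaTable,
) -> float:
    """National total: sum over counties and DR categories of
    area x category share x per-hectare value.

    ``per_ha_value`` maps ``(region, dr_category)`` (or just
    ``dr_category``) to a per-hectare value; region-specific values are
    selected through each county's region. Per-hectare inputs should
    already be averaged over soils unless soil shares are folded in
    upstream.
    """
    total = 0.0
    for _, row in areas.frame.iterrows():
        region = row["region"]
        for lab in DR_LABELS:
            share = float(row[f"share_{lab}"])
            key = (region, lab)
            if key in per_ha_value:
                value = per_ha_value[key]
            elif lab in per_ha_value:
                value = per_ha_value[lab]
            else:
                raise KeyError(
                    f"no per-hectare value for region={region!r}, category={lab!r}"
                )
            total += float(row["cereal_area_ha"]) * share * float(value)
    return total


def compare_scenarios(results: pd.DataFrame) -> pd.DataFrame:
    """Summarise strategy-level results into a Table-1-style report.

    ``results`` needs one row per strategy with columns: scenario,
    dr_category, soil, region, prop_damaging_year6, prop_damaging_annual,
    gross_profit, wheat_yield. Emits one row per scenario with means and
    (min, max) envelopes across regions, soils and categories.
    """
    required = {
        "scenario",
        "dr_category",
        "soil",
        "region",
        "prop_damaging_year6",
        "prop_damaging_annual",
        "gross_profit",
        "wheat_yield",
    }
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    if results.empty:
        raise ValueError("empty results table")
    rows = []
    for scenario, grp in results.groupby("scenario", sort=False):
        row = {"scenario": scenario, "n_strategies": len(grp)}
        for col in (
            "prop_damaging_year6",
            "prop_damaging_annual",
            "gross_profit",
            "wheat_yield",
        ):
            row[f"{col}_mean"] = float(grp[col].mean())
            row[f"{col}_min"] = float(grp[col].min())
            row[f"{col}_max"] = float(grp[col].max())
        rows.append(row)
    return pd.DataFrame(rows)
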