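"""Gross-margin economics with density-responsive winter-wheat yield.

Implements the bioeconomic accounting used to compare rotations: crop
output, itemised variable costs (herbicide, operations, other), gross
profit, and wheat yield weighted by the density-state distribution.
All numeric tables (prices, base yields, yield penalties) are editable
packaged fixtures in 2019 prices and are clearly labelled stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .density_model import (
    N_STATES,
    STATE_LABELS,
    DensityTrajectory,
    check_distribution,
)
from .strategies import CROPS, ManagementYear

__all__ = [
    "PriceTable",
    "YieldPenaltyTable",
    "BaseYieldTable",
    "EconYear",
    "RotationSummary",
    "wheat_yield",
    "year_costs",
    "gross_profit_year",
    "rotation_summary",
    "evaluate_rotation",
    "refine_and_average",
]

#: Crops with no marketable output (their "yield" is zero by definition).
ZERO_OUTPUT_CROPS = frozenset({"fallow", "cover_crop"})

OPERATION_TYPES = (
    "drilling",
    "inversion_plough",
    "min_till",
    "no_till",
    "spray_pass",
    "stale_seedbed_pass",
)

PENALTY_BOUNDS = ("lower", "central", "upper")


def _data_path(name: str) -> Path:
    with resources.as_file(resources.files("weedrot.data") / name) as p:
        return Path(p)


@dataclass
class PriceTable:
    """2019-style prices: outputs, herbicides, operations, other inputs."""

    crop_price: dict[str, float]  # GBP/t
    glyphosate_cost: float  # GBP/l
    selective_cost: float  # GBP/l
    operation_costs: dict[str, float]  # GBP/ha per pass
    other_costs: dict[str, float]  # GBP/ha per crop (fertiliser+seed+sundry)
    price_year: int = 2019

    def __post_init__(self) -> None:
        for name, table in (
            ("crop_price", self.crop_price),
            ("operation_costs", self.operation_costs),
            ("other_costs", self.other_costs),
        ):
            for k, v in table.items():
                if v < 0:
                    raise ValueError(f"negative price in {name}: {k}={v}")
        if self.glyphosate_cost < 0 or self.selective_cost < 0:
            raise ValueError("herbicide costs must be >= 0")
        for crop in CROPS:
            if crop not in self.crop_price:
                raise ValueError(f"crop {crop!r} missing from crop_price")
            if crop not in self.other_costs:
                raise ValueError(f"crop {crop!r} missing from other_costs")
        for op in OPERATION_TYPES:
            if op not in self.operation_costs:
                raise ValueError(f"operation {op!r} missing from operation_costs")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"section": "crop_price", "key": k, "value": v}
            for k, v in self.crop_price.items()
        ]
        rows += [
            {"section": "herbicide_cost", "key": "glyphosate", "value": self.glyphosate_cost},
            {"section": "herbicide_cost", "key": "selective", "value": self.selective_cost},
        ]
        rows += [
            {"section": "operation_cost", "key": k, "value": v}
            for k, v in self.operation_costs.items()
        ]
        rows += [
            {"section": "other_cost", "key": k, "value": v}
            for k, v in self.other_costs.items()
        ]
        rows.append({"section": "meta", "key": "price_year", "value": self.price_year})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PriceTable":
        def section(name):
            sub = frame[frame["section"] == name]
            return dict(zip(sub["key"], sub["value"].astype(float)))

        herb = section("herbicide_cost")
        meta = section("meta")
        return cls(
            crop_price=section("crop_price"),
            glyphosate_cost=herb["glyphosate"],
            selective_cost=herb["selective"],
            operation_costs=section("operation_cost"),
            other_costs=section("other_cost"),
            price_year=int(meta.get("price_year", 2019)),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PriceTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def load_default(cls) -> "PriceTable":
        return cls.from_csv(_data_path("prices.csv"))


@dataclass
class YieldPenaltyTable:
    """Proportional winter-wheat yield loss per density state.

    Only the two highest states carry a penalty; each has (lower,
    central, upper) limits for sensitivity analysis.
    """

    lower: np.ndarray
    central: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lower", "central", "upper"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_STATES,):
                raise ValueError(f"{name} penalties need {N_STATES} entries")
            setattr(self, name, arr)
        for arr in (self.lower, self.central, self.upper):
            if np.any(arr[:3] != 0.0):
                raise ValueError("absent/low/medium states must have zero penalty")
            if not (0.0 <= arr[3] <= arr[4] <= 1.0):
                raise ValueError("need 0 <= loss(high) <= loss(very_high) <= 1")
        if np.any(self.lower > self.central) or np.any(self.central > self.upper):
            raise ValueError("penalty limits must satisfy lower <= central <= upper")

    def losses(self, bound: str = "central") -> np.ndarray:
        if bound not in PENALTY_BOUNDS:
            raise ValueError(f"bound must be one of {PENALTY_BOUNDS}, got {bound!r}")
        return getattr(self, bound)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "state": STATE_LABELS,
                "lower": self.lower,
                "central": self.central,
                "upper": self.upper,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "YieldPenaltyTable":
        frame = pd.read_csv(path).set_index("state").loc[list(STATE_LABELS)]
        return cls(
            lower=frame["lower"].to_numpy(),
            central=frame["central"].to_numpy(),
            upper=frame["upper"].to_numpy(),
        )

    @classmethod
    def load_default(cls) -> "YieldPenaltyTable":
        return cls.from_csv(_data_path("yield_penalties.csv"))


@dataclass
class BaseYieldTable:
    """Potential (weed-free) yield in t/ha per (crop, soil, region)."""

    yields: dict[tuple[str, str, str], float]

    def __post_init__(self) -> None:
        for key, v in self.yields.items():
            if v <= 0:
                raise ValueError(f"base yield must be > 0 for {key}, got {v}")

    def base_yield(self, crop: str, soil: str, region: str) -> float:
        if crop in ZERO_OUTPUT_CROPS:
            return 0.0
        try:
            return self.yields[(crop, soil, region)]
        except KeyError:
            raise KeyError(
                f"no base yield for crop={crop!r}, soil={soil!r}, region={region!r}"
            ) from None

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"crop": c, "soil": s, "region": r, "yield_t_ha": v}
            for (c, s, r), v in sorted(self.yields.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BaseYieldTable":
        frame = pd.read_csv(path)
        return cls(
            yields={
                (r.crop, r.soil, r.region): float(r.yield_t_ha)
                for r in frame.itertuples()
            }
        )

    @classmethod
    def load_default(cls) -> "BaseYieldTable":
        return cls.from_csv(_data_path("base_yields.csv"))


# ---------------------------------------------------------------------------
# Per-year economics

@dataclass(frozen=True)
class EconYear:
    """One year's economic outcome (per hectare)."""

    crop: str
    output: float
    potential_output: float
    herbicide_cost: float
    operations_cost: float
    other_cost: float
    wheat_yield: float  # t/ha; 0 for non-wheat years

    @property
    def total_cost(self) -> float:
        return self.herbicide_cost + self.operations_cost + self.other_cost

    @property
    def gross_profit(self) -> float:
        return self.output - self.total_cost


def wheat_yield(
    base: float,
    distribution,
    penalties: YieldPenaltyTable,
    bound: str = "central",
) -> float:
    """Density-weighted winter-wheat yield: base * sum_s p_s (1 - loss_s)."""
    p = check_distribution(distribution)
    losses = penalties.losses(bound)
    return float(base * np.sum(p * (1.0 - losses)))


def year_costs(year: ManagementYear, prices: PriceTable) -> dict[str, float]:
    """Itemised variable costs for one management year (GBP/ha).

    herbicide = product cost of glyphosate + selectives; operations =
    fuel+labour passes (tillage, drilling, each spray, each stale-seedbed
    pass); other = fertiliser, seed and sundries for the crop.
    """
    if year.crop not in prices.other_costs:
        raise KeyError(f"crop {year.crop!r} not priced")
    op = prices.operation_costs
    herbicide = (
        year.glyphosate_dose * prices.glyphosate_cost
        + year.selective_dose * prices.selective_cost
    )
    spray_passes = year.glyphosate_applications + year.selective_applications
    operations = (
        op[year.tillage]
        + (op["drilling"] if year.sowing_window != "none" else 0.0)
        + spray_passes * op["spray_pass"]
        + year.n_stale_seedbeds * op["stale_seedbed_pass"]
    )
    other = prices.other_costs[year.crop]
    return {"herbicide": herbicide, "operations": operations, "other": other}


def gross_profit_year(
    year: ManagementYear,
    distribution,
    prices: PriceTable,
    base_yields: BaseYieldTable,
    penalties: YieldPenaltyTable,
    soil: str,
    region: str,
    bound: str = "central",
) -> EconYear:
    """Full per-year accounting; the identity output - costs = profit is
    exact by construction. Only winter wheat responds to weed density."""
    costs = year_costs(year, prices)
    base = base_yields.base_yield(year.crop, soil, region)
    price = prices.crop_price[year.crop]
    if year.crop == "winter_wheat":
        realised = wheat_yield(base, distribution, penalties, bound)
        wheat = realised
    else:
        check_distribution(distribution)
        realised = base
        wheat = 0.0
    return EconYear(
        crop=year.crop,
        output=realised * price,
        potential_output=base * price,
        herbicide_cost=costs["herbicide"],
        operations_cost=costs["operations"],
        other_cost=costs["other"],
        wheat_yield=wheat,
    )


@dataclass
class RotationSummary:
    """Rotation-level means with min/max envelopes across imputations."""

    mean_gross_profit: float
    mean_wheat_yield: float  # rotation wheat total / rotation length
    gross_profit_range: tuple[float, float]
    wheat_yield_range: tuple[float, float]
    per_imputation_gross_profit: np.ndarray
    per_imputation_wheat_yield: np.ndarray
    per_year: list[list[EconYear]]  # [imputation][year]


def rotation_summary(per_year_results: Sequence[Sequence[EconYear]]) -> RotationSummary:
    """Summarise per-imputation, per-year results over a rotation.

    Mean annual wheat yield follows the rotation-total / rotation-length
    convention so scenarios with different wheat frequencies compare on
    a per-year basis.
    """
    if not per_year_results or not per_year_results[0]:
        raise ValueError("no economic results to summarise")
    gp = np.array(
        [[y.gross_profit for y in imp] for imp in per_year_results]
    )  # (n_imp, T)
    wy = np.array([[y.wheat_yield for y in imp] for imp in per_year_results])
    gp_mean = gp.mean(axis=1)
    wy_mean = wy.sum(axis=1) / wy.shape[1]
    return RotationSummary(
        mean_gross_profit=float(gp_mean.mean()),
        mean_wheat_yield=float(wy_mean.mean()),
        gross_profit_range=(float(gp_mean.min()), float(gp_mean.max())),
        wheat_yield_range=(float(wy_mean.min()), float(wy_mean.max())),
        per_imputation_gross_profit=gp_mean,
        per_imputation_wheat_yield=wy_mean,
        per_year=[list(imp) for imp in per_year_results],
    )


def evaluate_rotation(
    years: Sequence[ManagementYear],
    trajectory: DensityTrajectory,
    prices: PriceTable,
    base_yields: BaseYieldTable,
    penalties: YieldPenaltyTable,
    soil: str,
    region: str,
    bound: str = "central",
) -> RotationSummary:
    """Economics of a whole plan: year t uses the trajectory's year-t
    distribution (the state the crop experiences), per imputation."""
    if trajectory.n_years != len(years):
        raise ValueError(
            f"trajectory covers {trajectory.n_years} years but plan has {len(years)}"
        )
    per_imp: list[list[EconYear]] = []
    for imp in trajectory.per_imputation:
        results = [
            gross_profit_year(
                year, imp[t + 1], prices, base_yields, penalties, soil, region, bound
            )
            for t, year in enumerate(years)
        ]
        per_imp.append(results)
    return rotation_summary(per_imp)


def refine_and_average(values: Iterable[float] | Mapping[str, float]) -> float:
    """Average finer-subcategory model outputs back to a coarse category
    (unweighted arithmetic mean)."""
    if isinstance(values, Mapping):
        values = list(values.values())
    else:
        values = list(values)
    if not values:
        raise ValueError("no subcategory values to average")
    return float(np.mean(values))
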