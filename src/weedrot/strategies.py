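"""Management strategies: rotations, validation, and switching sequences.

A :class:`Strategy` is a labelled 6-year sequence of per-year management
(crop, sowing window, tillage, stale seedbeds, herbicide programme) that
targets one initial condition (density-resistance class x soil x region).
Three scenarios are represented: business-as-usual (BAU, the ww-ww-osr
rotation), continuous winter wheat (CWW), and mitigation (MIT, the
diversified rotations shipped as editable CSV fixtures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CROPS",
    "SPRING_CROPS",
    "SOWING_WINDOWS",
    "TILLAGE_TYPES",
    "SOILS",
    "REGIONS",
    "DR_LABELS",
    "ManagementYear",
    "Strategy",
    "SequencePlan",
    "StrategyValidationError",
    "build_bau",
    "build_cww",
    "load_strategies",
    "load_default_mit_strategies",
    "strategies_to_frame",
    "save_strategies",
    "validate_mit_strategy",
    "make_sequence",
    "wheat_years",
    "spring_crop_years",
]

CROPS = (
    "winter_wheat",
    "winter_oilseed_rape",
    "spring_barley",
    "spring_beans",
    "spring_oats",
    "fallow",
    "cover_crop",
)
SPRING_CROPS = frozenset(c for c in CROPS if c.startswith("spring_"))
SOWING_WINDOWS = ("early_autumn", "late_autumn", "spring", "none")
TILLAGE_TYPES = ("inversion_plough", "min_till", "no_till")
SOILS = ("heavy", "medium", "light")
REGIONS = ("north", "central", "east")
DR_LABELS = ("LD-LR", "LD-HR", "HD-HR")

ROTATION_LENGTH = 6
SEQUENCE_CODES = ("BBB", "BBM", "BMM", "MMM")


class StrategyValidationError(ValueError):
    """Raised when a strategy or rotation file violates its contract."""


@dataclass(frozen=True)
class ManagementYear:
    """One year of field management within a rotation."""

    crop: str
    sowing_window: str
    tillage: str
    n_stale_seedbeds: int = 0
    glyphosate_applications: int = 0
    glyphosate_dose: float = 0.0  # litres/ha, total over the year
    selective_applications: int = 0
    selective_dose: float = 0.0  # litres/ha, total over the year
    seed_rate: float = 1.0  # multiplier relative to standard practice

    def __post_init__(self) -> None:
        if self.crop not in CROPS:
            raise StrategyValidationError(f"unknown crop {self.crop!r}")
        if self.sowing_window not in SOWING_WINDOWS:
            raise StrategyValidationError(
                f"unknown sowing window {self.sowing_window!r}"
            )
        if self.tillage not in TILLAGE_TYPES:
            raise StrategyValidationError(f"unknown tillage {self.tillage!r}")
        for name in (
            "n_stale_seedbeds",
            "glyphosate_applications",
            "glyphosate_dose",
            "selective_applications",
            "selective_dose",
            "seed_rate",
        ):
            if getattr(self, name) < 0:
                raise StrategyValidationError(f"{name} must be >= 0")
        # Stale seedbeds need pre-drilling time: only possible when sowing
        # is delayed to late autumn or spring.
        if self.n_stale_seedbeds > 0 and self.sowing_window not in (
            "late_autumn",
            "spring",
        ):
            raise StrategyValidationError(
                "stale seedbeds require late_autumn or spring sowing "
                f"(crop={self.crop}, sowing_window={self.sowing_window})"
            )


@dataclass(frozen=True)
class Strategy:
    """A 6-year rotation targeting one initial condition."""

    strategy_id: str
    scenario: str  # BAU | CWW | MIT
    dr_category: str
    soil: str
    region: str
    years: tuple[ManagementYear, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.scenario not in ("BAU", "CWW", "MIT"):
            raise StrategyValidationError(f"unknown scenario {self.scenario!r}")
        if self.dr_category not in DR_LABELS:
            raise StrategyValidationError(f"unknown DR category {self.dr_category!r}")
        if self.soil not in SOILS:
            raise StrategyValidationError(f"unknown soil {self.soil!r}")
        if self.region not in REGIONS:
            raise StrategyValidationError(f"unknown region {self.region!r}")
        if len(self.years) != ROTATION_LENGTH:
            raise StrategyValidationError(
                f"rotation must have exactly {ROTATION_LENGTH} years, "
                f"got {len(self.years)} ({self.strategy_id})"
            )

    @property
    def crops(self) -> tuple[str, ...]:
        return tuple(y.crop for y in self.years)

    def total(self, attr: str) -> float:
        return float(sum(getattr(y, attr) for y in self.years))


@dataclass(frozen=True)
class SequencePlan:
    """An 18-year sequence of three 6-year blocks (BAU or MIT)."""

    code: str
    years: tuple[ManagementYear, ...]
    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.code not in SEQUENCE_CODES:
            raise StrategyValidationError(f"unknown sequence code {self.code!r}")
        if len(self.years) != 3 * ROTATION_LENGTH:
            raise StrategyValidationError("sequence must be 18 years long")


def wheat_years(strategy: Strategy | Sequence[ManagementYear]) -> int:
    years = strategy.years if isinstance(strategy, Strategy) else strategy
    return sum(1 for y in years if y.crop == "winter_wheat")


def spring_crop_years(strategy: Strategy | Sequence[ManagementYear]) -> int:
    years = strategy.years if isinstance(strategy, Strategy) else strategy
    return sum(1 for y in years if y.crop in SPRING_CROPS)


def _bau_wheat_year() -> ManagementYear:
    # Late drilling with one stale seedbed already reflects current moves
    # against resistant populations.
    return ManagementYear(
        crop="winter_wheat",
        sowing_window="late_autumn",
        tillage="min_till",
        n_stale_seedbeds=1,
        glyphosate_applications=1,
        glyphosate_dose=1.5,
        selective_applications=2,
        selective_dose=2.0,
        seed_rate=1.0,
    )


def _bau_osr_year() -> ManagementYear:
    return ManagementYear(
        crop="winter_oilseed_rape",
        sowing_window="early_autumn",
        tillage="inversion_plough",
        n_stale_seedbeds=0,
        glyphosate_applications=0,
        glyphosate_dose=0.0,
        selective_applications=1,
        selective_dose=1.0,
        seed_rate=1.0,
    )


def build_bau(
    dr_category: str = "LD-LR", soil: str = "medium", region: str = "central"
) -> Strategy:
    """Business-as-usual: ww-ww-osr repeated to a 6-year rotation."""
    ww, osr = _bau_wheat_year(), _bau_osr_year()
    return Strategy(
        strategy_id=f"BAU_{dr_category}_{soil}_{region}",
        scenario="BAU",
        dr_category=dr_category,
        soil=soil,
        region=region,
        years=(ww, ww, osr, ww, ww, osr),
    )


def build_cww(
    dr_category: str = "LD-LR", soil: str = "medium", region: str = "central"
) -> Strategy:
    """Continuous winter wheat: the highest-value crop every year."""
    ww = _bau_wheat_year()
    return Strategy(
        strategy_id=f"CWW_{dr_category}_{soil}_{region}",
        scenario="CWW",
        dr_category=dr_category,
        soil=soil,
        region=region,
        years=(ww,) * ROTATION_LENGTH,
    )


# ---------------------------------------------------------------------------
# MIT validation

def validate_mit_strategy(
    strategy: Strategy, bau: Strategy | None = None
) -> list[str]:
    """Check a MIT strategy against the qualitative design constraints.

    Returns a list of violation messages (empty when valid):
    every MIT rotation has at least one spring crop and more stale
    seedbeds than BAU; high-resistance targets grow wheat less often
    than BAU and apply at most three times BAU's glyphosate; low-
    resistance (LD-LR) targets reduce total herbicide volume.
    """
    bau = bau or build_bau()
    problems: list[str] = []
    if spring_crop_years(strategy) < 1:
        problems.append("no spring crop in rotation")
    if strategy.total("n_stale_seedbeds") <= bau.total("n_stale_seedbeds"):
        problems.append("stale seedbeds not increased over BAU")
    if strategy.dr_category in ("LD-HR", "HD-HR"):
        if wheat_years(strategy) >= wheat_years(bau):
            problems.append("high-resistance target must grow wheat less than BAU")
        glyph = strategy.total("glyphosate_dose")
        if glyph > 3.0 * bau.total("glyphosate_dose") + 1e-9:
            problems.append("glyphosate dose exceeds three times BAU")
        if glyph < bau.total("glyphosate_dose") - 1e-9:
            problems.append("high-resistance target should not cut glyphosate below BAU")
    if strategy.dr_category == "LD-LR":
        total = strategy.total("glyphosate_dose") + strategy.total("selective_dose")
        bau_total = bau.total("glyphosate_dose") + bau.total("selective_dose")
        if total >= bau_total:
            problems.append("LD-LR target must reduce total herbicide volume vs BAU")
    return problems


# ---------------------------------------------------------------------------
# Serialisation

_YEAR_COLUMNS = [
    "crop",
    "sowing_window",
    "tillage",
    "n_stale_seedbeds",
    "glyphosate_applications",
    "glyphosate_dose",
    "selective_applications",
    "selective_dose",
    "seed_rate",
]
_HEADER_COLUMNS = ["strategy_id", "scenario", "dr_category", "soil", "region", "year_index"]


def strategies_to_frame(strategies: Iterable[Strategy]) -> pd.DataFrame:
    """One row per strategy-year, in the documented CSV schema."""
    rows = []
    for s in strategies:
        for i, y in enumerate(s.years):
            row = {
                "strategy_id": s.strategy_id,
                "scenario": s.scenario,
                "dr_category": s.dr_category,
                "soil": s.soil,
                "region": s.region,
                "year_index": i + 1,
            }
            row.update(asdict(y))
            rows.append(row)
    return pd.DataFrame(rows, columns=_HEADER_COLUMNS + _YEAR_COLUMNS)


def save_strategies(strategies: Iterable[Strategy], path: str | Path) -> None:
    path = Path(path)
    frame = strategies_to_frame(strategies)
    if path.suffix == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        frame.to_csv(path, index=False)


def _strategies_from_frame(frame: pd.DataFrame, validate: bool) -> list[Strategy]:
    missing = set(_HEADER_COLUMNS + _YEAR_COLUMNS) - set(frame.columns)
    if missing:
        raise StrategyValidationError(f"strategy table missing columns: {sorted(missing)}")
    strategies = []
    problems: list[str] = []
    bau = build_bau()
    for sid, grp in frame.groupby("strategy_id", sort=False):
        grp = grp.sort_values("year_index")
        years = tuple(
            ManagementYear(
                crop=r.crop,
                sowing_window=r.sowing_window,
                tillage=r.tillage,
                n_stale_seedbeds=int(r.n_stale_seedbeds),
                glyphosate_applications=int(r.glyphosate_applications),
                glyphosate_dose=float(r.glyphosate_dose),
                selective_applications=int(r.selective_applications),
                selective_dose=float(r.selective_dose),
                seed_rate=float(r.seed_rate),
            )
            for r in grp.itertuples()
        )
        head = grp.iloc[0]
        strategy = Strategy(
            strategy_id=str(sid),
            scenario=str(head.scenario),
            dr_category=str(head.dr_category),
            soil=str(head.soil),
            region=str(head.region),
            years=years,
        )
        if validate and strategy.scenario == "MIT":
            for msg in validate_mit_strategy(strategy, bau):
                problems.append(f"{sid}: {msg}")
        strategies.append(strategy)
    if problems:
        raise StrategyValidationError(
            "MIT strategy constraints violated:\n  " + "\n  ".join(problems)
        )
    return strategies


def load_strategies(path: str | Path, validate: bool = True) -> list[Strategy]:
    """Load strategies from the CSV/JSON schema, validating MIT rules."""
    path = Path(path)
    if path.suffix == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path)
    return _strategies_from_frame(frame, validate)


def load_default_mit_strategies(validate: bool = True) -> list[Strategy]:
    """The 27 packaged MIT fixture rotations (3 DR x 3 soils x 3 regions).

    These are labelled stand-ins constructed to satisfy the documented
    qualitative constraints; replace the CSV to use real rotations.
    """
    with resources.as_file(
        resources.files("weedrot.data") / "mit_strategies.csv"
    ) as p:
        return load_strategies(p, validate=validate)


def make_sequence(code: str, bau: Strategy, mit: Strategy) -> SequencePlan:
    """Resolve a switching code (BBB/BBM/BMM/MMM) into 18 years."""
    if code not in SEQUENCE_CODES:
        raise StrategyValidationError(
            f"unknown sequence code {code!r}; expected one of {SEQUENCE_CODES}"
        )
    blocks = tuple("BAU" if ch == "B" else "MIT" for ch in code)
    years: list[ManagementYear] = []
    for block in blocks:
        years.extend((bau if block == "BAU" else mit).years)
    return SequencePlan(code=code, years=tuple(years), blocks=blocks)
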