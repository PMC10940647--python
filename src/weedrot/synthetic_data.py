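"""Synthetic inputs with the statistical structure of the field study.

Generates every input the pipeline needs — quadrat surveys, resistance
assays, management histories, transition datasets from a known model,
price tables and county areas — so all downstream stages are testable
without any download. All generators are pure functions of
(configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import density_model as dm
from .econmod import BaseYieldTable, PriceTable, YieldPenaltyTable
from .comparison import CountyAreaTable
from .strategies import ManagementYear

__all__ = [
    "COUNTY_REGIONS",
    "FieldSurvey",
    "ResistanceAssaySet",
    "SyntheticConfig",
    "gen_survey_data",
    "gen_management_histories",
    "gen_covariate_rich_histories",
    "gen_transition_dataset",
    "gen_price_tables",
    "gen_county_areas",
    "default_true_model",
    "surveys_to_frame",
    "assays_to_frame",
]

#: The 13 surveyed counties and the broad region each was assigned to.
#: (Stand-in mapping; the study's own county->region table is in its SI.)
COUNTY_REGIONS: dict[str, str] = {
    "North Yorkshire": "north",
    "East Riding of Yorkshire": "north",
    "South Yorkshire": "north",
    "Nottinghamshire": "north",
    "Leicestershire": "central",
    "Warwickshire": "central",
    "Northamptonshire": "central",
    "Oxfordshire": "central",
    "Buckinghamshire": "central",
    "Bedfordshire": "central",
    "Lincolnshire": "east",
    "Cambridgeshire": "east",
    "Suffolk": "east",
}

DR_CATEGORIES = ("LD-LR", "LD-HR", "HD-HR")

#: Per-category quadrat-state sampling probabilities (stand-ins; low-
#: density categories concentrate in states 0-2, high-density in 3-4).
CATEGORY_STATE_PROFILES: dict[str, tuple[float, ...]] = {
    "LD-LR": (0.55, 0.30, 0.12, 0.02, 0.01),
    "LD-HR": (0.40, 0.35, 0.20, 0.04, 0.01),
    "HD-HR": (0.05, 0.10, 0.20, 0.35, 0.30),
}


@dataclass(frozen=True)
class FieldSurvey:
    """One field-year quadrat survey of ordinal density states."""

    field_id: str
    county: str
    region: str
    soil: str
    year: int
    grid: np.ndarray  # integer states 0..4, shape (rows, cols)
    latent_category: str | None = None  # generating DR class, if synthetic

    def __post_init__(self) -> None:
        if self.county in COUNTY_REGIONS and COUNTY_REGIONS[self.county] != self.region:
            raise ValueError(
                f"region {self.region!r} inconsistent with county {self.county!r}"
            )
        grid = np.asarray(self.grid)
        if grid.size == 0:
            raise ValueError("survey grid must be non-empty")
        if np.any((grid < 0) | (grid > 4)):
            raise ValueError("quadrat states must be in 0..4")
        object.__setattr__(self, "grid", grid)


@dataclass(frozen=True)
class ResistanceAssaySet:
    """Glasshouse assay mortalities for the two selective herbicides."""

    field_id: str
    mortality_atlantis: float
    mortality_cycloxydim: float

    def __post_init__(self) -> None:
        for name in ("mortality_atlantis", "mortality_cycloxydim"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Controls for the survey/assay generator. ``seed`` is mandatory."""

    seed: int
    n_fields: int = 125
    grid_dims: tuple[int, int] = (20, 20)
    category_mix: tuple[float, float, float] = (0.14, 0.56, 0.30)
    # Beta noise for assay mortality: separable means around the 0.72
    # resistance cut-off, concentration keeps boundary cases plausible.
    mortality_mean_susceptible: float = 0.90
    mortality_mean_resistant: float = 0.40
    mortality_concentration: float = 50.0

    def __post_init__(self) -> None:
        if self.n_fields <= 0:
            raise ValueError("n_fields must be positive")
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid dimensions must be positive")
        mix = np.asarray(self.category_mix, dtype=float)
        if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("category_mix must be 3 non-negative proportions summing to 1")


def gen_survey_data(
    cfg: SyntheticConfig,
) -> tuple[list[FieldSurvey], list[ResistanceAssaySet]]:
    """Generate field surveys and matching resistance assays.

    Each field gets a latent DR category from ``category_mix``; quadrat
    states come from the category's state profile and assay mortalities
    from beta distributions whose means sit either side of the 72%
    mortality cut-off. Byte-identical for identical (config, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    counties = list(COUNTY_REGIONS)
    soils = ("heavy", "medium", "light")
    categories = rng.choice(len(DR_CATEGORIES), size=cfg.n_fields, p=cfg.category_mix)
    conc = cfg.mortality_concentration
    surveys: list[FieldSurvey] = []
    assays: list[ResistanceAssaySet] = []
    for i in range(cfg.n_fields):
        cat = DR_CATEGORIES[int(categories[i])]
        county = counties[i % len(counties)]
        fid = f"F{i:04d}"
        grid = rng.choice(
            5, size=cfg.grid_dims, p=CATEGORY_STATE_PROFILES[cat]
        ).astype(np.int8)
        surveys.append(
            FieldSurvey(
                field_id=fid,
                county=county,
                region=COUNTY_REGIONS[county],
                soil=soils[i % len(soils)],
                year=2019,
                grid=grid,
                latent_category=cat,
            )
        )
        mean = (
            cfg.mortality_mean_susceptible
            if cat == "LD-LR"
            else cfg.mortality_mean_resistant
        )
        a, b = mean * conc, (1.0 - mean) * conc
        assays.append(
            ResistanceAssaySet(
                field_id=fid,
                mortality_atlantis=float(rng.beta(a, b)),
                mortality_cycloxydim=float(rng.beta(a, b)),
            )
        )
    return surveys, assays


def surveys_to_frame(surveys: Sequence[FieldSurvey]) -> pd.DataFrame:
    """Tidy export: one row per field-year-quadrat."""
    rows = []
    for s in surveys:
        for (r, c), state in np.ndenumerate(np.atleast_2d(s.grid)):
            rows.append(
                {
                    "field_id": s.field_id,
                    "county": s.county,
                    "region": s.region,
                    "soil": s.soil,
                    "year": s.year,
                    "row": r,
                    "col": c,
                    "state": int(state),
                }
            )
    return pd.DataFrame(rows)


def assays_to_frame(assays: Sequence[ResistanceAssaySet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "field_id": a.field_id,
                "mortality_atlantis": a.mortality_atlantis,
                "mortality_cycloxydim": a.mortality_cycloxydim,
            }
            for a in assays
        ]
    )


# ---------------------------------------------------------------------------
# Management histories

#: Year-to-year crop transition frequencies (rows renormalised after any
#: withheld transitions are removed). Dominated by the BAU crops.
DEFAULT_CROP_TRANSITIONS: dict[str, dict[str, float]] = {
    "winter_wheat": {
        "winter_wheat": 0.45,
        "winter_oilseed_rape": 0.35,
        "spring_barley": 0.10,
        "spring_beans": 0.05,
        "spring_oats": 0.05,
    },
    "winter_oilseed_rape": {
        "winter_wheat": 0.80,
        "spring_barley": 0.12,
        "spring_beans": 0.08,
    },
    "spring_barley": {"winter_wheat": 0.60, "winter_oilseed_rape": 0.25, "spring_barley": 0.15},
    "spring_beans": {"winter_wheat": 0.70, "spring_barley": 0.30},
    "spring_oats": {"winter_wheat": 0.70, "winter_oilseed_rape": 0.30},
}

#: Per-crop management templates used when generating histories.
_CROP_TEMPLATES: dict[str, dict] = {
    "winter_wheat": dict(
        sowing_window="late_autumn", tillage="min_till", stale=(0, 1, 2),
        glyph_apps=(0, 1, 2), selective_apps=(1, 2, 3),
    ),
    "winter_oilseed_rape": dict(
        sowing_window="early_autumn", tillage="inversion_plough", stale=(0,),
        glyph_apps=(0, 1), selective_apps=(0, 1, 2),
    ),
    "spring_barley": dict(
        sowing_window="spring", tillage="min_till", stale=(0, 1, 2),
        glyph_apps=(0, 1, 2), selective_apps=(0, 1),
    ),
    "spring_beans": dict(
        sowing_window="spring", tillage="no_till", stale=(0, 1, 2),
        glyph_apps=(0, 1, 2), selective_apps=(0, 1),
    ),
    "spring_oats": dict(
        sowing_window="spring", tillage="min_till", stale=(0, 1),
        glyph_apps=(0, 1), selective_apps=(0, 1),
    ),
}

HISTORY_COLUMNS = [
    "field_id",
    "rotation_id",
    "year",
    "crop",
    "sowing_window",
    "tillage",
    "n_stale_seedbeds",
    "glyphosate_applications",
    "glyphosate_dose",
    "selective_applications",
    "selective_dose",
    "seed_rate",
    "resistance",
]


def gen_management_histories(
    surveys: Sequence[FieldSurvey],
    seed: int,
    n_years: int = 6,
    crop_transition_probs: Mapping[str, Mapping[str, float]] | None = None,
    withheld_transitions: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Per-field multi-year management records (one row per field-year).

    Crop sequences follow a configurable transition-frequency table;
    ``withheld_transitions`` removes (prev, next) pairs by construction
    so the missing-transition imputation path can be exercised
    reproducibly.
    """
    if not surveys:
        raise ValueError("empty survey set")
    probs = {
        prev: dict(nxt)
        for prev, nxt in (crop_transition_probs or DEFAULT_CROP_TRANSITIONS).items()
    }
    for prev, nxt in withheld_transitions:
        probs.get(prev, {}).pop(nxt, None)
        if prev in probs and not probs[prev]:
            raise ValueError(f"withholding left crop {prev!r} with no successor")
    rng = np.random.default_rng(seed)
    rows = []
    for s in surveys:
        rotation_id = f"rot{rng.integers(0, 6)}"
        resistance = "low" if (s.latent_category or "LD-HR") == "LD-LR" else "high"
        crop = "winter_wheat" if rng.random() < 0.7 else "winter_oilseed_rape"
        for year_offset in range(n_years + 1):
            if year_offset > 0:
                options = probs[crop]
                names = list(options)
                weights = np.array([options[n] for n in names], dtype=float)
                crop = str(rng.choice(names, p=weights / weights.sum()))
            t = _CROP_TEMPLATES[crop]
            stale = int(rng.choice(t["stale"]))
            if t["sowing_window"] not in ("late_autumn", "spring"):
                stale = 0
            glyph = max(int(rng.choice(t["glyph_apps"])), 1 if stale else 0)
            selective = int(rng.choice(t["selective_apps"]))
            rows.append(
                {
                    "field_id": s.field_id,
                    "rotation_id": rotation_id,
                    "year": s.year + year_offset,
                    "crop": crop,
                    "sowing_window": t["sowing_window"],
                    "tillage": t["tillage"],
                    "n_stale_seedbeds": stale,
                    "glyphosate_applications": glyph,
                    "glyphosate_dose": round(1.5 * glyph, 3),
                    "selective_applications": selective,
                    "selective_dose": round(1.0 * selective, 3),
                    "seed_rate": float(rng.choice([0.9, 1.0, 1.1])),
                    "resistance": resistance,
                }
            )
    return pd.DataFrame(rows, columns=HISTORY_COLUMNS)


def gen_covariate_rich_histories(
    n_fields: int,
    n_years: int,
    seed: int,
    crops: Sequence[str] = ("winter_wheat", "winter_oilseed_rape", "spring_barley",
                            "spring_beans", "spring_oats"),
) -> pd.DataFrame:
    """Histories with management randomised independently of crop.

    Breaks the crop->management collinearity of realistic records, which
    makes these the right input for parameter-recovery experiments on
    the transition model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_fields):
        fid = f"R{i:04d}"
        rotation_id = f"rot{rng.integers(0, 6)}"
        resistance = "low" if rng.random() < 0.5 else "high"
        for year in range(n_years + 1):
            sowing = str(rng.choice(["early_autumn", "late_autumn", "spring", "none"]))
            stale = int(rng.integers(0, 3)) if sowing in ("late_autumn", "spring") else 0
            glyph = int(rng.integers(0, 3))
            selective = int(rng.integers(0, 3))
            rows.append(
                {
                    "field_id": fid,
                    "rotation_id": rotation_id,
                    "year": 2019 + year,
                    "crop": str(rng.choice(list(crops))),
                    "sowing_window": sowing,
                    "tillage": str(rng.choice(["inversion_plough", "min_till", "no_till"])),
                    "n_stale_seedbeds": stale,
                    "glyphosate_applications": glyph,
                    "glyphosate_dose": 1.5 * glyph,
                    "selective_applications": selective,
                    "selective_dose": 1.0 * selective,
                    "seed_rate": float(rng.choice([0.8, 0.9, 1.0, 1.1, 1.2])),
                    "resistance": resistance,
                }
            )
    return pd.DataFrame(rows, columns=HISTORY_COLUMNS)


# ---------------------------------------------------------------------------
# Transition datasets from a known model

def default_true_model(n_imputations: int = 1, seed: int = 0) -> dm.TransitionModel:
    """A plausible generating model: states persist, cultural controls
    (stale seedbeds, spring sowing, delayed drilling, glyphosate)
    push densities down, high resistance pushes them up."""
    return dm.make_known_model(
        cutpoints=(-0.5, 1.0, 2.5, 4.0),
        beta={
            "prev_state:low": 1.0,
            "prev_state:medium": 2.0,
            "prev_state:high": 3.0,
            "prev_state:very_high": 4.0,
            "sowing:late_autumn": -0.3,
            "sowing:spring": -0.8,
            "sowing:none": -1.0,
            "tillage:min_till": 0.1,
            "tillage:no_till": 0.2,
            "resistance:high": 0.8,
            "n_stale_seedbeds": -0.35,
            "glyphosate_applications": -0.25,
            "selective_applications": -0.20,
            "seed_rate_dev": -0.5,
        },
        n_imputations=n_imputations,
        seed=seed,
    )


def gen_transition_dataset(
    true_model: dm.TransitionModel,
    histories: pd.DataFrame,
    seed: int,
    surveys: Sequence[FieldSurvey] | None = None,
    n_quadrats: int = 50,
    imputation_index: int = 0,
) -> pd.DataFrame:
    """Observed (state_t, covariates, state_t+1) records from a known model.

    Quadrats start from the field's survey grid when ``surveys`` is
    given (uniform random states otherwise) and evolve year by year;
    next states are sampled from the exact categorical distribution the
    model implies, so the output supports parameter recovery. One record
    per quadrat-transition in the histories.
    """
    if len(true_model.imputations) <= imputation_index:
        raise ValueError("true_model lacks the requested imputation")
    rng = np.random.default_rng(seed)
    survey_by_field = {s.field_id: s for s in surveys} if surveys else {}
    rows = []
    for field_id, grp in histories.groupby("field_id", sort=False):
        grp = grp.sort_values("year")
        if field_id in survey_by_field:
            states = survey_by_field[field_id].grid.ravel().astype(int).copy()
        else:
            states = rng.integers(0, dm.N_STATES, size=n_quadrats)
        years = list(grp.itertuples())
        for prev_row, row in zip(years[:-1], years[1:]):
            year = ManagementYear(
                crop=row.crop,
                sowing_window=row.sowing_window,
                tillage=row.tillage,
                n_stale_seedbeds=int(row.n_stale_seedbeds),
                glyphosate_applications=int(row.glyphosate_applications),
                glyphosate_dose=float(row.glyphosate_dose),
                selective_applications=int(row.selective_applications),
                selective_dose=float(row.selective_dose),
                seed_rate=float(row.seed_rate),
            )
            cov = dm.encode_covariates(year, prev_row.crop, 0, str(row.resistance))
            cov = dm.CovariateVector(
                **{
                    **cov.__dict__,
                    "field_id": str(field_id),
                    "rotation_id": str(row.rotation_id),
                }
            )
            M = dm.transition_matrix(true_model, cov, imputation_index)
            next_states = np.empty_like(states)
            for s in range(dm.N_STATES):
                mask = states == s
                if mask.any():
                    next_states[mask] = rng.choice(
                        dm.N_STATES, size=int(mask.sum()), p=M[s]
                    )
            for st, nx in zip(states, next_states):
                rows.append(
                    {
                        "field_id": str(field_id),
                        "rotation_id": str(row.rotation_id),
                        "year": int(row.year),
                        "prev_state": int(st),
                        "next_state": int(nx),
                        "crop_transition": cov.crop_transition,
                        "sowing_window": cov.sowing_window,
                        "tillage": cov.tillage,
                        "n_stale_seedbeds": cov.n_stale_seedbeds,
                        "glyphosate_applications": cov.glyphosate_applications,
                        "selective_applications": cov.selective_applications,
                        "seed_rate": cov.seed_rate,
                        "resistance": cov.resistance,
                    }
                )
            states = next_states
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged fixture tables

def gen_price_tables() -> tuple[PriceTable, BaseYieldTable, YieldPenaltyTable]:
    """Deterministic packaged 2019-price fixtures (labelled stand-ins)."""
    return (
        PriceTable.load_default(),
        BaseYieldTable.load_default(),
        YieldPenaltyTable.load_default(),
    )


def gen_county_areas(counties: Sequence[str] | None = None) -> CountyAreaTable:
    """County cereal areas with DR-category shares (packaged stand-ins)."""
    table = CountyAreaTable.load_default()
    if counties is not None:
        unknown = set(counties) - set(table.counties)
        if unknown:
            raise KeyError(f"counties missing from the area table: {sorted(unknown)}")
        table = CountyAreaTable(
            table.frame[table.frame["county"].isin(counties)].reset_index(drop=True)
        )
    return table
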