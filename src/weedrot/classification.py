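"""Field-level classification of weed density and herbicide resistance.

Maps raw quadrat surveys and glasshouse assay mortalities to ordinal
density categories, a low/high resistance dichotomy, and the combined
density-resistance (DR) classes used to target management strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DensityCategory",
    "DRCategory",
    "RESISTANCE_MORTALITY_CUTOFF",
    "LD_DENSITY_CATEGORIES",
    "mean_density_score",
    "density_category",
    "classify_resistance",
    "assign_dr_category",
    "classify_fields",
    "summarise_prevalence",
]

#: Mean assay mortality at or above which a population counts as *low*
#: resistance (the herbicides still kill most plants).
RESISTANCE_MORTALITY_CUTOFF = 0.72

N_STATES = 5


class DensityCategory(str, Enum):
    """Ordinal field-level density category from the mean quadrat score."""

    ABSENT = "absent"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    VERY_HIGH = "very_high"


#: Density categories counted as "low density" in the field-level dichotomy.
#: Only the two highest categories carry an economic wheat-yield impact.
LD_DENSITY_CATEGORIES = frozenset(
    {DensityCategory.ABSENT, DensityCategory.LOW, DensityCategory.MEDIUM}
)


@dataclass(frozen=True)
class DRCategory:
    """Combined density-resistance class (e.g. ``LD-HR``).

    ``anomalous`` flags the high-density / low-resistance combination,
    which is not expected under sane management and is never silently
    dropped.
    """

    label: str
    anomalous: bool = False

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def density_category(score: float) -> DensityCategory:
    """Categorise a mean quadrat score.

    Cut-offs: [0, 0.5] absent; (0.5, 1.5) low; [1.5, 2.5) medium;
    [2.5, 3.5) high; [3.5, inf) very high.
    """
    if not np.isfinite(score) or score < 0:
        raise ValueError(f"invalid mean density score: {score!r}")
    if score <= 0.5:
        return DensityCategory.ABSENT
    if score < 1.5:
        return DensityCategory.LOW
    if score < 2.5:
        return DensityCategory.MEDIUM
    if score < 3.5:
        return DensityCategory.HIGH
    return DensityCategory.VERY_HIGH


def mean_density_score(grid) -> tuple[float, DensityCategory]:
    """Mean ordinal density state of a quadrat grid, plus its category.

    Parameters
    ----------
    grid
        Array-like of quadrat states, each in {0, 1, 2, 3, 4}.
    """
    arr = np.asarray(grid)
    if arr.size == 0:
        raise ValueError("empty quadrat grid")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("quadrat grid must be numeric")
    if np.any((arr < 0) | (arr > N_STATES - 1)) or np.any(arr != np.round(arr)):
        raise ValueError("quadrat states must be integers in 0..4")
    score = float(arr.mean())
    return score, density_category(score)


def classify_resistance(
    mortality_atlantis: float, mortality_cycloxydim: float
) -> str:
    """Classify selective-herbicide resistance as ``"low"`` or ``"high"``.

    The unweighted mean of the two assay mortalities is compared with
    :data:`RESISTANCE_MORTALITY_CUTOFF`; mortality at or above the
    cut-off means the herbicides remain effective, i.e. LOW resistance.
    """
    for name, m in (
        ("mortality_atlantis", mortality_atlantis),
        ("mortality_cycloxydim", mortality_cycloxydim),
    ):
        if m is None or not np.isfinite(m):
            raise ValueError(f"missing assay mortality: {name}")
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {m}")
    mean = (mortality_atlantis + mortality_cycloxydim) / 2.0
    return "low" if mean >= RESISTANCE_MORTALITY_CUTOFF else "high"


def assign_dr_category(
    density: DensityCategory | str, resistance: str
) -> DRCategory:
    """Combine the density and resistance dichotomies into a DR class."""
    density = DensityCategory(density)
    if resistance not in ("low", "high"):
        raise ValueError(f"resistance must be 'low' or 'high', got {resistance!r}")
    low_density = density in LD_DENSITY_CATEGORIES
    if low_density:
        return DRCategory("LD-LR" if resistance == "low" else "LD-HR")
    if resistance == "high":
        return DRCategory("HD-HR")
    # High density with effective herbicides: flag, never drop.
    return DRCategory("HD-HR", anomalous=True)


def classify_fields(surveys: Iterable, assays: Iterable) -> pd.DataFrame:
    """Classify every surveyed field; one output row per field.

    ``surveys`` yield objects with ``field_id`` and ``grid``; ``assays``
    yield objects with ``field_id``, ``mortality_atlantis`` and
    ``mortality_cycloxydim``.
    """
    assay_by_field = {a.field_id: a for a in assays}
    rows = []
    for s in surveys:
        if s.field_id not in assay_by_field:
            raise ValueError(f"no resistance assay for field {s.field_id!r}")
        a = assay_by_field[s.field_id]
        score, dens = mean_density_score(s.grid)
        resistance = classify_resistance(a.mortality_atlantis, a.mortality_cycloxydim)
        dr = assign_dr_category(dens, resistance)
        rows.append(
            {
                "field_id": s.field_id,
                "score": score,
                "density_category": dens.value,
                "mean_mortality": (a.mortality_atlantis + a.mortality_cycloxydim) / 2.0,
                "resistance": resistance,
                "dr_category": dr.label,
                "anomalous": dr.anomalous,
            }
        )
    if not rows:
        raise ValueError("no fields to classify")
    return pd.DataFrame(rows)


def summarise_prevalence(
    classified: pd.DataFrame | Sequence[DRCategory | str],
) -> Mapping[str, float]:
    """Proportions of fields per DR category (anomalous bucketed apart)."""
    if isinstance(classified, pd.DataFrame):
        if classified.empty:
            raise ValueError("empty classification table")
        labels = [
            "anomalous" if bool(anom) else lab
            for lab, anom in zip(classified["dr_category"], classified["anomalous"])
        ]
    else:
        classified = list(classified)
        if not classified:
            raise ValueError("no classified fields")
        labels = []
        for c in classified:
            if isinstance(c, DRCategory):
                labels.append("anomalous" if c.anomalous else c.label)
            else:
                labels.append(str(c))
    counts = pd.Series(labels).value_counts()
    props = (counts / counts.sum()).to_dict()
    for key in ("LD-LR", "LD-HR", "HD-HR"):
        props.setdefault(key, 0.0)
    return props
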