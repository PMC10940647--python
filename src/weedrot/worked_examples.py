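"""Reproduce the published worked-example arithmetic.

Each target is a pure function of other printed quantities (table cells
and stated reference figures, packaged in ``data/worked_examples.json``)
evaluated through the package's own comparison operations. The harness
is deliberately sensitive: perturbing any input changes the computed
value and fails the check.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from . import comparison
from .density_model import check_distribution

__all__ = ["load_worked_examples", "evaluate_target", "reproduce_worked_examples"]


def load_worked_examples() -> dict:
    text = (resources.files("weedrot.data") / "worked_examples.json").read_text()
    return json.loads(text)


def _switchable_mass(distribution) -> float:
    """Percentage of grid cells below the top state (able to move up)."""
    p = check_distribution(distribution)
    return float(100.0 * p[:-1].sum())


def evaluate_target(spec: dict) -> float:
    kind = spec["kind"]
    inputs = spec["inputs"]
    if kind == "opportunity_cost":
        return float(comparison.opportunity_cost(inputs["gp_bau"], inputs["gp_mit"]))
    if kind == "productivity_cost":
        return float(comparison.productivity_cost(inputs["y_bau"], inputs["y_mit"]))
    if kind == "percent_of_reference":
        ndigits = inputs.get("ndigits", 1)
        return float(
            comparison.percent_of_reference(
                inputs["value"], inputs["reference"], ndigits=int(ndigits)
            )
        )
    if kind == "switchable_mass":
        return _switchable_mass(inputs["distribution"])
    if kind == "relative_reduction":
        return float(
            comparison.relative_reduction(
                inputs["baseline"], inputs["treatment"],
                ndigits=int(inputs.get("ndigits", 1)),
            )
        )
    raise ValueError(f"unknown worked-example kind {kind!r}")


def reproduce_worked_examples(atol: float = 5e-3) -> pd.DataFrame:
    """Evaluate every target; returns a pass/fail report."""
    rows = []
    for target_id, spec in load_worked_examples().items():
        computed = evaluate_target(spec)
        expected = float(spec["expected"])
        rows.append(
            {
                "target": target_id,
                "computed": computed,
                "expected": expected,
                "units": spec.get("units", ""),
                "n_inputs": len(spec["inputs"]),
                "passed": bool(np.isclose(computed, expected, atol=atol, rtol=0)),
            }
        )
    return pd.DataFrame(rows)
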