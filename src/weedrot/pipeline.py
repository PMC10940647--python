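"""End-to-end orchestration: configuration, seeding, stage wiring and
run manifests.

The pipeline wires the five analysis stages together on synthetic (or
user-supplied) inputs: generate/classify surveys, assemble strategies,
fit the transition model, simulate density under every strategy,
evaluate the economics, and emit comparison tables plus a JSON run
manifest. One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn`` in stage order, so stages can
be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification as cls
from . import comparison as cmp
from . import density_model as dm
from . import econmod as em
from . import strategies as st
from . import synthetic_data as sd
from .worked_examples import reproduce_worked_examples

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "designed_initial_distribution"]

STAGE_NAMES = (
    "synthetic_data",
    "classification",
    "strategies",
    "density_model",
    "econmod",
    "comparison",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a run reads; no stage touches anything undeclared."""

    seed: int
    out_dir: str = "weedrot_out"
    n_fields: int = 60
    grid_dims: tuple[int, int] = (10, 10)
    n_imputations: int = 37
    n_history_years: int = 6
    n_quadrats_per_field: int = 20
    penalty_bound: str = "central"
    scenarios: tuple[str, ...] = ("BAU", "CWW", "MIT")
    sequence_codes: tuple[str, ...] = ("BBB", "BBM", "BMM", "MMM")
    strategy_file: str | None = None  # None -> packaged MIT fixtures
    price_file: str | None = None
    base_yield_file: str | None = None
    penalty_file: str | None = None
    county_file: str | None = None
    withheld_transitions: tuple[tuple[str, str], ...] = ()
    run_worst_case: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.grid_dims = tuple(self.grid_dims)  # type: ignore[assignment]
        self.scenarios = tuple(self.scenarios)  # type: ignore[assignment]
        self.sequence_codes = tuple(self.sequence_codes)  # type: ignore[assignment]
        self.withheld_transitions = tuple(
            tuple(p) for p in self.withheld_transitions
        )  # type: ignore[assignment]
        if self.penalty_bound not in em.PENALTY_BOUNDS:
            raise ValueError(f"penalty_bound must be one of {em.PENALTY_BOUNDS}")
        for name in ("strategy_file", "price_file", "base_yield_file",
                     "penalty_file", "county_file"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} does not exist: {path}")

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["grid_dims"] = list(self.grid_dims)
        payload["scenarios"] = list(self.scenarios)
        payload["sequence_codes"] = list(self.sequence_codes)
        payload["withheld_transitions"] = [list(p) for p in self.withheld_transitions]
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        path = Path(source)
        payload = yaml.safe_load(path.read_text() if path.exists() else str(source))
        return cls(**payload)


#: Designed-for initial density distributions per DR class (stand-ins;
#: LD classes start concentrated in the lower states, HD in the upper).
def designed_initial_distribution(dr_category: str) -> np.ndarray:
    profiles = sd.CATEGORY_STATE_PROFILES
    if dr_category not in profiles:
        raise KeyError(f"unknown DR category {dr_category!r}")
    return np.asarray(profiles[dr_category], dtype=float)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resistance_of(dr: str) -> str:
    return "low" if dr.endswith("LR") else "high"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest.

    Every stage's outputs are written to ``cfg.out_dir`` before the next
    stage consumes them; partial outputs are retained when a stage
    fails. Re-running the same config is bit-identical apart from
    timestamps.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: s.generate_state(1)[0]
        for name, s in zip(STAGE_NAMES, np.random.SeedSequence(cfg.seed).spawn(len(STAGE_NAMES)))
    }
    manifest: dict = {
        "config": yaml.safe_load(cfg.to_yaml()),
        "stage_seeds": {k: int(v) for k, v in stage_seeds.items()},
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrap

    # -- stage 0/1: synthetic surveys + classification ------------------
    @stage("synthetic_data")
    def _synth():
        scfg = sd.SyntheticConfig(
            seed=int(stage_seeds["synthetic_data"]),
            n_fields=cfg.n_fields,
            grid_dims=cfg.grid_dims,
        )
        surveys, assays = sd.gen_survey_data(scfg)
        sd.surveys_to_frame(surveys).to_csv(out / "surveys.csv", index=False)
        sd.assays_to_frame(assays).to_csv(out / "assays.csv", index=False)
        return surveys, assays

    surveys, assays = _synth

    @stage("classification")
    def _classify():
        table = cls.classify_fields(surveys, assays)
        table.to_csv(out / "classification.csv", index=False)
        return table

    classified = _classify

    # -- stage 2: strategies -------------------------------------------
    @stage("strategies")
    def _strategies():
        if cfg.strategy_file:
            mit = st.load_strategies(cfg.strategy_file)
        else:
            mit = st.load_default_mit_strategies()
        bundle = list(mit) if "MIT" in cfg.scenarios else []
        for dr in st.DR_LABELS:
            for soil in st.SOILS:
                for region in st.REGIONS:
                    if "BAU" in cfg.scenarios:
                        bundle.append(st.build_bau(dr, soil, region))
                    if "CWW" in cfg.scenarios:
                        bundle.append(st.build_cww(dr, soil, region))
        st.save_strategies(bundle, out / "strategies.csv")
        return bundle

    bundle = _strategies

    # -- stage 3: transition model -------------------------------------
    @stage("density_model")
    def _fit():
        true_model = sd.default_true_model(seed=int(stage_seeds["density_model"]))
        histories = sd.gen_management_histories(
            surveys,
            seed=int(stage_seeds["density_model"]) ^ 0x5EED,
            n_years=cfg.n_history_years,
            withheld_transitions=cfg.withheld_transitions,
        )
        histories.to_csv(out / "histories.csv", index=False)
        records = sd.gen_transition_dataset(
            true_model,
            histories,
            seed=int(stage_seeds["density_model"]) ^ 0x7A11,
            n_quadrats=cfg.n_quadrats_per_field,
        )
        records.to_csv(out / "transitions.csv", index=False)
        model = dm.fit_transition_model(
            records, n_imputations=cfg.n_imputations,
            seed=int(stage_seeds["density_model"]),
        )
        model.to_json(out / "model.json")
        return model

    model = _fit

    # -- stage 4: density simulation + economics -----------------------
    prices = em.PriceTable.from_csv(cfg.price_file) if cfg.price_file else em.PriceTable.load_default()
    base_yields = (
        em.BaseYieldTable.from_csv(cfg.base_yield_file)
        if cfg.base_yield_file
        else em.BaseYieldTable.load_default()
    )
    penalties = (
        em.YieldPenaltyTable.from_csv(cfg.penalty_file)
        if cfg.penalty_file
        else em.YieldPenaltyTable.load_default()
    )

    @stage("econmod")
    def _econ():
        rows = []
        traj_rows = []
        for s in bundle:
            initial = designed_initial_distribution(s.dr_category)
            resistance = _resistance_of(s.dr_category)
            traj = dm.simulate_density(model, s, initial, resistance)
            summary = em.evaluate_rotation(
                s.years, traj, prices, base_yields, penalties,
                s.soil, s.region, bound=cfg.penalty_bound,
            )
            damaging = traj.prop_damaging()  # (n_imp, 7)
            rows.append(
                {
                    "strategy_id": s.strategy_id,
                    "scenario": s.scenario,
                    "dr_category": s.dr_category,
                    "soil": s.soil,
                    "region": s.region,
                    "prop_damaging_year6": float(damaging[:, -1].mean()),
                    "prop_damaging_annual": float(damaging[:, 1:].mean()),
                    "gross_profit": summary.mean_gross_profit,
                    "gross_profit_min": summary.gross_profit_range[0],
                    "gross_profit_max": summary.gross_profit_range[1],
                    "wheat_yield": summary.mean_wheat_yield,
                    "wheat_yield_min": summary.wheat_yield_range[0],
                    "wheat_yield_max": summary.wheat_yield_range[1],
                }
            )
            frame = traj.to_frame()
            frame.insert(0, "strategy_id", s.strategy_id)
            traj_rows.append(frame)
        pd.concat(traj_rows, ignore_index=True).to_csv(
            out / "trajectories.csv", index=False
        )
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "strategy_results.csv", index=False)
        return frame

    results = _econ

    # -- stage 5: comparison -------------------------------------------
    @stage("comparison")
    def _compare():
        report = cmp.compare_scenarios(results)
        report.to_csv(out / "scenario_summary.csv", index=False)

        areas = (
            cmp.CountyAreaTable.from_csv(cfg.county_file)
            if cfg.county_file
            else cmp.CountyAreaTable.load_default()
        )
        current_rows = []
        if {"BAU", "MIT"} <= set(cfg.scenarios):
            opp_values: dict[tuple[str, str], float] = {}
            prod_values: dict[tuple[str, str], float] = {}
            for dr in st.DR_LABELS:
                for region in st.REGIONS:
                    sub = results[
                        (results["dr_category"] == dr) & (results["region"] == region)
                    ]
                    gp = {
                        sc: em.refine_and_average(
                            sub[sub["scenario"] == sc]["gross_profit"]
                        )
                        for sc in ("BAU", "MIT")
                    }
                    wy = {
                        sc: em.refine_and_average(
                            sub[sub["scenario"] == sc]["wheat_yield"]
                        )
                        for sc in ("BAU", "MIT")
                    }
                    opp = float(cmp.opportunity_cost(gp["BAU"], gp["MIT"]))
                    prod = float(cmp.productivity_cost(wy["BAU"], wy["MIT"]))
                    opp_values[(region, dr)] = opp
                    prod_values[(region, dr)] = prod
                    current_rows.append(
                        {
                            "dr_category": dr,
                            "region": region,
                            "gross_profit_bau": gp["BAU"],
                            "gross_profit_mit": gp["MIT"],
                            "wheat_yield_bau": wy["BAU"],
                            "wheat_yield_mit": wy["MIT"],
                            "opportunity_cost": opp,
                            "productivity_cost": prod,
                        }
                    )
            current = pd.DataFrame(current_rows)
            current.to_csv(out / "switching_current.csv", index=False)
            scaled = {
                "scaled_opportunity_cost": cmp.scale_up(opp_values, areas),
                "scaled_productivity_cost": cmp.scale_up(prod_values, areas),
            }
            (out / "scaled_up.json").write_text(json.dumps(scaled, indent=1))

        # worst-case 18-year sequences
        if cfg.run_worst_case and {"BAU", "MIT"} <= set(cfg.scenarios):
            seq_rows = []
            mit_by_key = {
                (s.dr_category, s.soil, s.region): s
                for s in bundle
                if s.scenario == "MIT"
            }
            for (dr, soil, region), mit in mit_by_key.items():
                bau = st.build_bau(dr, soil, region)
                per_code: dict[str, em.RotationSummary] = {}
                for code in cfg.sequence_codes:
                    plan = st.make_sequence(code, bau, mit)
                    traj = dm.simulate_density(
                        model, plan, dm.WORST_CASE_DISTRIBUTION, "high"
                    )
                    per_code[code] = em.evaluate_rotation(
                        plan.years, traj, prices, base_yields, penalties,
                        soil, region, bound=cfg.penalty_bound,
                    )
                if "BBB" not in per_code:
                    continue
                ref = per_code["BBB"]
                for code, summary in per_code.items():
                    seq_rows.append(
                        {
                            "dr_category": dr,
                            "soil": soil,
                            "region": region,
                            "sequence": code,
                            "gross_profit": summary.mean_gross_profit,
                            "wheat_yield": summary.mean_wheat_yield,
                            "opportunity_cost": float(
                                cmp.opportunity_cost(
                                    ref.mean_gross_profit, summary.mean_gross_profit
                                )
                            ),
                            "productivity_cost": float(
                                cmp.productivity_cost(
                                    ref.mean_wheat_yield, summary.mean_wheat_yield
                                )
                            ),
                        }
                    )
            pd.DataFrame(seq_rows).to_csv(out / "switching_worst_case.csv", index=False)

        worked = reproduce_worked_examples()
        worked.to_csv(out / "worked_examples.csv", index=False)
        return report

    _compare

    prevalence = cls.summarise_prevalence(classified)
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv")) if p.is_file()
    }
    manifest["prevalence"] = {k: float(v) for k, v in prevalence.items()}
    manifest["model_diagnostics"] = dm._jsonable(model.diagnostics)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
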