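"""Density-state transition model: fitting and forward simulation.

The weed population in a field is tracked as a distribution over five
ordinal density states. Year-on-year state transitions follow a
proportional-odds cumulative-logit model,

    P(next_state <= k | x) = logistic(c_k - eta),
    eta = x @ beta + u_crop_transition + u_rotation + u_field,

with fixed effects for the previous state and management covariates and
Gaussian random effects for crop transition, rotation and field.
Estimation uses penalised maximum likelihood (ridge penalties on the
random effects whose scales are updated by an outer EM-style loop).
Uncertainty from crop transitions never observed in the training data is
propagated by multiple imputation: each imputation draws an independent
effect for every unobserved transition from the fitted crop-transition
random-effect distribution.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .strategies import CROPS, ManagementYear, SequencePlan, Strategy

logger = logging.getLogger(__name__)

__all__ = [
    "STATE_LABELS",
    "N_STATES",
    "WORST_CASE_DISTRIBUTION",
    "check_distribution",
    "prop_damaging",
    "CovariateVector",
    "encode_covariates",
    "TransitionModel",
    "ImputationParams",
    "ModelFitError",
    "fit_transition_model",
    "transition_matrix",
    "simulate_density",
    "DensityTrajectory",
    "make_known_model",
    "identity_like_model",
]

STATE_LABELS = ("absent", "low", "medium", "high", "very_high")
N_STATES = 5

#: Initial distribution for the worst-case explorations: 70% of grid
#: cells sit below the top state and can still move up.
WORST_CASE_DISTRIBUTION = np.array([0.1, 0.1, 0.2, 0.3, 0.3])

RANDOM_EFFECT_GROUPS = ("crop_transition", "rotation", "field")


class ModelFitError(RuntimeError):
    """Raised for degenerate data or (in strict mode) non-convergence."""


def check_distribution(p, tol: float = 1e-9) -> np.ndarray:
    """Validate a 5-state density distribution and return it as an array."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (N_STATES,):
        raise ValueError(f"distribution must have {N_STATES} entries, got {arr.shape}")
    if np.any(arr < -tol) or np.any(arr > 1 + tol):
        raise ValueError("distribution entries must lie in [0, 1]")
    if abs(arr.sum() - 1.0) > tol:
        raise ValueError(f"distribution must sum to 1 (got {arr.sum():.12f})")
    return arr


def prop_damaging(p) -> float:
    """Proportion of the field in the two economically damaging states."""
    arr = check_distribution(p)
    return float(arr[3] + arr[4])


# ---------------------------------------------------------------------------
# Covariate encoding

@dataclass(frozen=True)
class CovariateVector:
    """Covariates driving one year's state transition."""

    prev_state: int
    crop_transition: str
    sowing_window: str
    tillage: str
    n_stale_seedbeds: float
    glyphosate_applications: float
    selective_applications: float
    seed_rate: float
    resistance: str
    field_id: str | None = None
    rotation_id: str | None = None
    missing_transition: bool = False


# Fixed-effect design: baselines are prev_state=absent, early_autumn
# sowing, inversion plough, low resistance.
FIXED_EFFECT_NAMES = (
    "prev_state:low",
    "prev_state:medium",
    "prev_state:high",
    "prev_state:very_high",
    "sowing:late_autumn",
    "sowing:spring",
    "sowing:none",
    "tillage:min_till",
    "tillage:no_till",
    "resistance:high",
    "n_stale_seedbeds",
    "glyphosate_applications",
    "selective_applications",
    "seed_rate_dev",
)


def apply_proxies(crop: str, proxy_map: Mapping[str, str] | None) -> str:
    if proxy_map and crop in proxy_map:
        stand_in = proxy_map[crop]
        logger.info("proxy crop transition: %s stands in for %s", stand_in, crop)
        return stand_in
    return crop


def encode_covariates(
    year: ManagementYear,
    prev_crop: str,
    prev_state: int,
    resistance: str,
    vocab: "TransitionModel | Sequence[str] | None" = None,
    proxy_map: Mapping[str, str] | None = None,
) -> CovariateVector:
    """Deterministically encode one management year into covariates.

    If ``vocab`` (a fitted model or a collection of known crop
    transitions) is given, transitions outside it are flagged
    ``missing_transition`` so the imputation path handles them; they are
    never silently zeroed. ``proxy_map`` substitutes stand-in crops for
    the transition label before the lookup, logging each application.
    """
    for crop in (prev_crop, year.crop):
        if crop not in CROPS:
            raise ValueError(f"unregistered crop name {crop!r}")
    if resistance not in ("low", "high"):
        raise ValueError(f"resistance must be 'low' or 'high', got {resistance!r}")
    if not 0 <= int(prev_state) < N_STATES:
        raise ValueError(f"prev_state must be in 0..{N_STATES - 1}")
    transition = (
        f"{apply_proxies(prev_crop, proxy_map)}->{apply_proxies(year.crop, proxy_map)}"
    )
    missing = False
    if vocab is not None:
        known = (
            vocab.crop_transitions
            if isinstance(vocab, TransitionModel)
            else tuple(vocab)
        )
        missing = transition not in known
    return CovariateVector(
        prev_state=int(prev_state),
        crop_transition=transition,
        sowing_window=year.sowing_window,
        tillage=year.tillage,
        n_stale_seedbeds=float(year.n_stale_seedbeds),
        glyphosate_applications=float(year.glyphosate_applications),
        selective_applications=float(year.selective_applications),
        seed_rate=float(year.seed_rate),
        resistance=resistance,
        missing_transition=missing,
    )


def _fixed_design_row(cov: CovariateVector) -> np.ndarray:
    x = np.zeros(len(FIXED_EFFECT_NAMES))
    if cov.prev_state > 0:
        x[cov.prev_state - 1] = 1.0
    if cov.sowing_window == "late_autumn":
        x[4] = 1.0
    elif cov.sowing_window == "spring":
        x[5] = 1.0
    elif cov.sowing_window == "none":
        x[6] = 1.0
    if cov.tillage == "min_till":
        x[7] = 1.0
    elif cov.tillage == "no_till":
        x[8] = 1.0
    if cov.resistance == "high":
        x[9] = 1.0
    x[10] = cov.n_stale_seedbeds
    x[11] = cov.glyphosate_applications
    x[12] = cov.selective_applications
    x[13] = cov.seed_rate - 1.0
    return x


# ---------------------------------------------------------------------------
# Model containers

@dataclass
class ImputationParams:
    """One imputation's coefficient set."""

    cutpoints: np.ndarray  # strictly increasing, length 4
    beta: dict[str, float]
    u: dict[str, dict[str, float]]  # group -> level -> effect
    sigma: dict[str, float]  # group -> random-effect scale
    seed: int  # drives draws for unobserved crop transitions

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.cutpoints.shape != (N_STATES - 1,):
            raise ValueError("need 4 cutpoints for 5 states")
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        missing = set(FIXED_EFFECT_NAMES) - set(self.beta)
        if missing:
            raise ValueError(f"missing fixed-effect coefficients: {sorted(missing)}")


@dataclass
class TransitionModel:
    """Fitted (or hand-specified) transition model across imputations."""

    imputations: list[ImputationParams]
    crop_transitions: tuple[str, ...] = ()
    rotations: tuple[str, ...] = ()
    fields: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)
    beta_se: dict[str, float] = field(default_factory=dict)
    proxy_map: dict[str, str] = field(default_factory=dict)
    imputed_transitions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_imputations(self) -> int:
        return len(self.imputations)

    def coef_table(self) -> pd.DataFrame:
        """Fixed-effect estimates with Wald 95% intervals (first imputation)."""
        imp = self.imputations[0]
        rows = []
        for name in FIXED_EFFECT_NAMES:
            est = imp.beta[name]
            se = self.beta_se.get(name, np.nan)
            rows.append(
                {
                    "coefficient": name,
                    "estimate": est,
                    "se": se,
                    "ci_low": est - 1.96 * se,
                    "ci_high": est + 1.96 * se,
                }
            )
        return pd.DataFrame(rows)

    def _transition_effect(self, name: str, imp_index: int) -> float:
        """Crop-transition effect; unobserved transitions get a stable
        per-imputation draw from N(0, sigma_crop_transition)."""
        imp = self.imputations[imp_index]
        group = imp.u.setdefault("crop_transition", {})
        if name in group:
            return group[name]
        sigma = imp.sigma.get("crop_transition", 0.0)
        rng = np.random.default_rng([imp.seed & 0xFFFFFFFF, zlib.crc32(name.encode())])
        effect = float(rng.normal(0.0, sigma))
        group[name] = effect
        self.imputed_transitions.append((imp_index, name))
        logger.info(
            "imputed effect for unobserved crop transition %r (imputation %d): %.4f",
            name,
            imp_index,
            effect,
        )
        return effect

    def linear_predictor(self, cov: CovariateVector, imp_index: int) -> float:
        imp = self.imputations[imp_index]
        x = _fixed_design_row(cov)
        eta = float(sum(x[i] * imp.beta[n] for i, n in enumerate(FIXED_EFFECT_NAMES)))
        eta += self._transition_effect(cov.crop_transition, imp_index)
        if cov.rotation_id is not None:
            eta += imp.u.get("rotation", {}).get(cov.rotation_id, 0.0)
        if cov.field_id is not None:
            eta += imp.u.get("field", {}).get(cov.field_id, 0.0)
        return eta

    # -- serialisation ------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "crop_transitions": list(self.crop_transitions),
            "rotations": list(self.rotations),
            "fields": list(self.fields),
            "diagnostics": _jsonable(self.diagnostics),
            "beta_se": self.beta_se,
            "proxy_map": self.proxy_map,
            "imputations": [
                {
                    "cutpoints": imp.cutpoints.tolist(),
                    "beta": imp.beta,
                    "u": imp.u,
                    "sigma": imp.sigma,
                    "seed": int(imp.seed),
                }
                for imp in self.imputations
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TransitionModel":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = source
        payload = json.loads(text)
        imputations = [
            ImputationParams(
                cutpoints=np.array(d["cutpoints"]),
                beta=d["beta"],
                u={g: dict(v) for g, v in d["u"].items()},
                sigma=d["sigma"],
                seed=int(d["seed"]),
            )
            for d in payload["imputations"]
        ]
        return cls(
            imputations=imputations,
            crop_transitions=tuple(payload["crop_transitions"]),
            rotations=tuple(payload["rotations"]),
            fields=tuple(payload["fields"]),
            diagnostics=payload.get("diagnostics", {}),
            beta_se=payload.get("beta_se", {}),
            proxy_map=payload.get("proxy_map", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def make_known_model(
    cutpoints,
    beta: Mapping[str, float] | None = None,
    crop_transition_effects: Mapping[str, float] | None = None,
    sigma: Mapping[str, float] | None = None,
    n_imputations: int = 1,
    seed: int = 0,
) -> TransitionModel:
    """Build a fully specified model from known coefficients.

    Unspecified fixed effects default to zero. Used for synthetic-data
    generation, oracle tests and parameter-recovery studies.
    """
    full_beta = {name: 0.0 for name in FIXED_EFFECT_NAMES}
    if beta:
        unknown = set(beta) - set(FIXED_EFFECT_NAMES)
        if unknown:
            raise ValueError(f"unknown coefficient names: {sorted(unknown)}")
        full_beta.update({k: float(v) for k, v in beta.items()})
    u_ct = dict(crop_transition_effects or {})
    sigmas = {g: 0.0 for g in RANDOM_EFFECT_GROUPS}
    if sigma:
        sigmas.update({k: float(v) for k, v in sigma.items()})
    seeds = np.random.SeedSequence(seed).generate_state(n_imputations)
    imputations = [
        ImputationParams(
            cutpoints=np.asarray(cutpoints, dtype=float),
            beta=dict(full_beta),
            u={"crop_transition": dict(u_ct), "rotation": {}, "field": {}},
            sigma=dict(sigmas),
            seed=int(s),
        )
        for s in seeds
    ]
    return TransitionModel(
        imputations=imputations,
        crop_transitions=tuple(u_ct),
        diagnostics={"source": "known"},
    )


def identity_like_model() -> TransitionModel:
    """A model whose transition matrix is (numerically) the identity."""
    return make_known_model(
        cutpoints=(50.0, 150.0, 250.0, 350.0),
        beta={
            "prev_state:low": 100.0,
            "prev_state:medium": 200.0,
            "prev_state:high": 300.0,
            "prev_state:very_high": 400.0,
        },
    )


# ---------------------------------------------------------------------------
# Fitting

REQUIRED_RECORD_COLUMNS = (
    "prev_state",
    "next_state",
    "crop_transition",
    "sowing_window",
    "tillage",
    "n_stale_seedbeds",
    "glyphosate_applications",
    "selective_applications",
    "seed_rate",
    "resistance",
    "field_id",
    "rotation_id",
)


def _build_design(records: pd.DataFrame):
    X = np.zeros((len(records), len(FIXED_EFFECT_NAMES)))
    prev = records["prev_state"].to_numpy(int)
    for s in range(1, N_STATES):
        X[prev == s, s - 1] = 1.0
    X[:, 4] = (records["sowing_window"] == "late_autumn").to_numpy(float)
    X[:, 5] = (records["sowing_window"] == "spring").to_numpy(float)
    X[:, 6] = (records["sowing_window"] == "none").to_numpy(float)
    X[:, 7] = (records["tillage"] == "min_till").to_numpy(float)
    X[:, 8] = (records["tillage"] == "no_till").to_numpy(float)
    X[:, 9] = (records["resistance"] == "high").to_numpy(float)
    X[:, 10] = records["n_stale_seedbeds"].to_numpy(float)
    X[:, 11] = records["glyphosate_applications"].to_numpy(float)
    X[:, 12] = records["selective_applications"].to_numpy(float)
    X[:, 13] = records["seed_rate"].to_numpy(float) - 1.0
    return X


def _cutpoints_from_theta(t: np.ndarray) -> np.ndarray:
    c = np.empty(N_STATES - 1)
    c[0] = t[0]
    c[1:] = t[0] + np.cumsum(np.exp(t[1:]))
    return c


def _nll_and_grad(theta, X, y, group_idx, group_sizes, sigmas):
    n, p = X.shape
    ncut = N_STATES - 1
    c = _cutpoints_from_theta(theta[:ncut])
    beta = theta[ncut : ncut + p]
    offset = ncut + p
    eta = X @ beta
    u_blocks = []
    for (idx, size), sig in zip(zip(group_idx, group_sizes), sigmas):
        u = theta[offset : offset + size]
        u_blocks.append(u)
        if size:
            eta = eta + u[idx]
        offset += size

    upper = np.where(y < ncut, c[np.minimum(y, ncut - 1)] - eta, np.inf)
    lower = np.where(y > 0, c[np.maximum(y - 1, 0)] - eta, -np.inf)
    Fu = np.where(np.isinf(upper), 1.0, expit(upper))
    Fl = np.where(np.isinf(lower), 0.0, expit(lower))
    prob = np.clip(Fu - Fl, 1e-300, None)
    nll = -np.sum(np.log(prob))

    fu = np.where(np.isinf(upper), 0.0, Fu * (1.0 - Fu))
    fl = np.where(np.isinf(lower), 0.0, Fl * (1.0 - Fl))
    g_eta = (fl - fu) / prob  # d log(prob) / d eta
    grad = np.zeros_like(theta)
    # cutpoints: record i contributes +fu/p to c[y_i] and -fl/p to c[y_i-1]
    gc = np.zeros(ncut)
    np.add.at(gc, np.minimum(y, ncut - 1), np.where(y < ncut, fu / prob, 0.0))
    np.add.at(gc, np.maximum(y - 1, 0), np.where(y > 0, -fl / prob, 0.0))
    grad[0] = -np.sum(gc)
    for j in range(1, ncut):
        grad[j] = -np.sum(gc[j:]) * np.exp(theta[j])
    grad[ncut : ncut + p] = -(X.T @ g_eta)
    offset = ncut + p
    for (idx, size), sig, u in zip(zip(group_idx, group_sizes), sigmas, u_blocks):
        if size:
            gu = -np.bincount(idx, weights=g_eta, minlength=size)
            nll += 0.5 * np.sum(u**2) / sig**2
            gu += u / sig**2
            grad[offset : offset + size] = gu
        offset += size
    return nll, grad


def fit_transition_model(
    records: pd.DataFrame,
    n_imputations: int = 37,
    seed: int = 0,
    sigma_floor: float = 0.1,
    outer_iterations: int = 3,
    strict: bool = False,
) -> TransitionModel:
    """Fit the hierarchical cumulative-logit transition model.

    ``records`` needs one row per observed quadrat transition with the
    columns in :data:`REQUIRED_RECORD_COLUMNS`. Returns a model carrying
    ``n_imputations`` coefficient sets; with complete data the sets are
    identical and imputation only affects crop transitions that were
    never observed, each of which receives one independent random-effect
    draw per imputation at prediction time.
    """
    missing = set(REQUIRED_RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ModelFitError("no transition records")
    y = records["next_state"].to_numpy(int)
    states_seen = set(y) | set(records["prev_state"].astype(int))
    if len(set(y)) < 2:
        raise ModelFitError(
            "degenerate data: all observed next states identical "
            f"(state {y[0]})"
        )
    if not states_seen <= set(range(N_STATES)):
        raise ValueError("states must be integers in 0..4")

    X = _build_design(records)
    group_levels = []
    group_idx = []
    for col in ("crop_transition", "rotation_id", "field_id"):
        codes, levels = pd.factorize(records[col].astype(str))
        group_idx.append(codes)
        group_levels.append(list(levels))
    group_sizes = [len(lv) for lv in group_levels]
    p = X.shape[1]
    ncut = N_STATES - 1
    n_params = ncut + p + sum(group_sizes)

    theta = np.zeros(n_params)
    theta[:ncut] = [-1.0, np.log(1.0), np.log(1.0), np.log(1.0)]
    sigmas = np.array([1.0, 1.0, 1.0])
    result = None
    for _ in range(outer_iterations):
        result = minimize(
            _nll_and_grad,
            theta,
            args=(X, y, group_idx, group_sizes, sigmas),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "maxfun": 2000},
        )
        theta = result.x
        offset = ncut + p
        for g, size in enumerate(group_sizes):
            u = theta[offset : offset + size]
            if size > 1:
                sigmas[g] = max(sigma_floor, float(np.sqrt(np.mean(u**2))))
            offset += size

    converged = bool(result.success) or float(np.linalg.norm(result.jac)) < 1e-2 * max(
        1.0, len(records) ** 0.5
    )
    diagnostics = {
        "converged": converged,
        "message": str(result.message),
        "nll": float(result.fun),
        "grad_norm": float(np.linalg.norm(result.jac)),
        "n_iterations": int(result.nit),
        "n_records": int(len(records)),
        "sigmas": {
            g: float(s) for g, s in zip(RANDOM_EFFECT_GROUPS, sigmas)
        },
    }
    if strict and not converged:
        raise ModelFitError(f"optimiser did not converge: {diagnostics}")
    if not converged:
        logger.warning("transition model fit did not fully converge: %s", diagnostics)

    beta_se = _fixed_effect_se(theta, X, y, group_idx, group_sizes, sigmas)
    cut = _cutpoints_from_theta(theta[:ncut])
    beta = {n: float(v) for n, v in zip(FIXED_EFFECT_NAMES, theta[ncut : ncut + p])}
    u: dict[str, dict[str, float]] = {}
    offset = ncut + p
    for gname, levels, size in zip(RANDOM_EFFECT_GROUPS, group_levels, group_sizes):
        u[gname] = {
            str(lv): float(v) for lv, v in zip(levels, theta[offset : offset + size])
        }
        offset += size

    imp_seeds = np.random.SeedSequence(seed).generate_state(n_imputations)
    imputations = [
        ImputationParams(
            cutpoints=cut.copy(),
            beta=dict(beta),
            u={g: dict(v) for g, v in u.items()},
            sigma={g: float(s) for g, s in zip(RANDOM_EFFECT_GROUPS, sigmas)},
            seed=int(s),
        )
        for s in imp_seeds
    ]
    return TransitionModel(
        imputations=imputations,
        crop_transitions=tuple(group_levels[0]),
        rotations=tuple(group_levels[1]),
        fields=tuple(group_levels[2]),
        diagnostics=diagnostics,
        beta_se=beta_se,
    )


def _fixed_effect_se(theta, X, y, group_idx, group_sizes, sigmas) -> dict[str, float]:
    """Wald standard errors for cutpoints+beta via a finite-difference
    Hessian of the penalised objective (random effects held fixed)."""
    ncut = N_STATES - 1
    p = X.shape[1]
    k = ncut + p
    eps = 1e-5
    H = np.zeros((k, k))
    base = theta.copy()
    for j in range(k):
        tp = base.copy()
        tp[j] += eps
        tm = base.copy()
        tm[j] -= eps
        _, gp = _nll_and_grad(tp, X, y, group_idx, group_sizes, sigmas)
        _, gm = _nll_and_grad(tm, X, y, group_idx, group_sizes, sigmas)
        H[j] = (gp[:k] - gm[:k]) / (2 * eps)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - pathological fits
        se = np.full(k, np.nan)
    return {n: float(se[ncut + i]) for i, n in enumerate(FIXED_EFFECT_NAMES)}


# ---------------------------------------------------------------------------
# Simulation

def transition_matrix(
    model: TransitionModel, cov: CovariateVector, imputation_index: int = 0
) -> np.ndarray:
    """5x5 row-stochastic matrix implied by the model at these covariates.

    Row ``s`` is the next-state distribution given ``prev_state = s``.
    """
    imp = model.imputations[imputation_index]
    M = np.empty((N_STATES, N_STATES))
    for s in range(N_STATES):
        eta = model.linear_predictor(replace(cov, prev_state=s), imputation_index)
        cdf = np.concatenate([expit(imp.cutpoints - eta), [1.0]])
        M[s] = np.diff(cdf, prepend=0.0)
    # guard against tiny negative round-off
    M = np.clip(M, 0.0, None)
    M /= M.sum(axis=1, keepdims=True)
    return M


@dataclass
class DensityTrajectory:
    """Per-imputation density-state trajectories for years 0..T."""

    per_imputation: np.ndarray  # shape (n_imputations, T+1, 5)

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_imputation, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != N_STATES:
            raise ValueError("expected shape (n_imputations, T+1, 5)")
        for imp in arr:
            for year in imp:
                check_distribution(year)
        self.per_imputation = arr

    @property
    def n_years(self) -> int:
        return self.per_imputation.shape[1] - 1

    @property
    def mean(self) -> np.ndarray:
        m = self.per_imputation.mean(axis=0)
        return m / m.sum(axis=1, keepdims=True)

    @property
    def lower(self) -> np.ndarray:
        return self.per_imputation.min(axis=0)

    @property
    def upper(self) -> np.ndarray:
        return self.per_imputation.max(axis=0)

    def prop_damaging(self) -> np.ndarray:
        """Per-imputation damaging proportion, shape (n_imputations, T+1)."""
        return self.per_imputation[:, :, 3] + self.per_imputation[:, :, 4]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, imp in enumerate(self.per_imputation):
            for t, dist in enumerate(imp):
                for s, prop in enumerate(dist):
                    rows.append(
                        {
                            "imputation": i,
                            "year": t,
                            "state": STATE_LABELS[s],
                            "proportion": prop,
                        }
                    )
        return pd.DataFrame(rows)


def simulate_density(
    model: TransitionModel,
    plan: Strategy | SequencePlan | Sequence[ManagementYear],
    initial,
    resistance: str,
    seed: int | None = None,
    initial_prev_crop: str | None = None,
    proxy_map: Mapping[str, str] | None = None,
) -> DensityTrajectory:
    """Project the density-state distribution forward under a plan.

    For every imputation the distribution is updated year-on-year as
    ``p_{t+1} = p_t @ M_t`` with ``M_t`` the transition matrix for year
    t's covariates. Resistance is held fixed throughout (no evolution).
    The returned trajectory includes year 0, so index 6 reads "at year
    6". The update is deterministic; ``seed`` is accepted for interface
    symmetry but unused (unobserved-transition draws are keyed to the
    model's own per-imputation seeds).
    """
    years = plan.years if hasattr(plan, "years") else tuple(plan)
    if not years:
        raise ValueError("empty management plan")
    p0 = check_distribution(initial)
    proxy_map = dict(model.proxy_map or {}) | dict(proxy_map or {})
    prev_crop0 = initial_prev_crop or years[-1].crop  # rotation wrap-around
    trajectories = np.empty((model.n_imputations, len(years) + 1, N_STATES))
    for i in range(model.n_imputations):
        p = p0.copy()
        trajectories[i, 0] = p
        prev_crop = prev_crop0
        for t, year in enumerate(years):
            cov = encode_covariates(
                year, prev_crop, 0, resistance, vocab=model, proxy_map=proxy_map
            )
            M = transition_matrix(model, cov, i)
            p = p @ M
            check_distribution(p)
            trajectories[i, t + 1] = p
            prev_crop = year.crop
    return DensityTrajectory(per_imputation=trajectories)
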