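"""Two-step particle-swarm calibration of the cell-solute model.

The fit minimises an L1 cost: for each species X with observation set of
size Omega_X, the mean absolute difference between nondimensionalised
predictions and measurements, summed over species,

    J(theta) = sum_X (1/Omega_X) sum_i |F_X,i(theta) - Y_X,i| / ref_X,i.

Oxygen observations are normalised by the condition's ambient level, glucose
by the initial medium concentration, viability is already a fraction of the
seeded density, and VEGF (which starts at zero) by the block's maximum
observed value.

Because oxygen/glucose/viability dynamics are mutually coupled but
independent of VEGF, the calibration splits into two swarm runs: step 1 fits
the ten transport/consumption/death constants against blocks (a)-(c);
step 2 then fits the six VEGF constants against block (d) with the step-1
result frozen.  Diffusivities in the medium are held at nominal values
throughout (screening ranks them as non-influential or they are
literature-constrained).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    LOG_SCALE_PARAMETERS,
    MMHG_PER_PERCENT,
    PARAMETER_BOUNDS,
    ParameterSet,
    calibration_bounds,
)
from .synthetic import (
    BLOCK_NAMES,
    ExperimentalDataset,
    SolverSettings,
    StudyDesign,
    predict_blocks,
)

__all__ = [
    "STEP1_PARAMETERS",
    "STEP2_PARAMETERS",
    "FIXED_PARAMETERS",
    "CostSpec",
    "SwarmConfig",
    "CalibrationResult",
    "TwoStepResult",
    "make_forward",
    "cost",
    "pso_minimize",
    "calibrate_two_step",
    "calibration_spread",
]

logger = logging.getLogger(__name__)

#: Step-1 free parameters: oxygen/glucose transport & consumption plus death.
STEP1_PARAMETERS: tuple[str, ...] = (
    "delta_0", "delta_c", "delta_s",
    "D_c_gel", "c_half", "M_c",
    "D_s_gel", "s_half", "M_s", "A",
)
#: Step-2 free parameters: VEGF transport, turnover and secretion.
STEP2_PARAMETERS: tuple[str, ...] = (
    "D_v_gel", "K_v", "c_tau", "n_tau", "alpha", "beta",
)
#: Held at nominal values throughout (plus the n_max metadata).
FIXED_PARAMETERS: tuple[str, ...] = ("D_c_med", "D_s_med", "D_v_med")

_BLOCK_VALUE = {
    "oxygen": "value_mmhg",
    "glucose": "value_mM",
    "viability": "viable_fraction",
    "vegf": "value_pg_ml",
}


# ---------------------------------------------------------------------------
# Cost
# ---------------------------------------------------------------------------


@dataclass
class CostSpec:
    """Observation blocks entering the cost, with their normalisations."""

    blocks: dict[str, pd.DataFrame]
    normalizers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("CostSpec requires at least one observation block")
        for name, df in self.blocks.items():
            if name not in BLOCK_NAMES:
                raise ValueError(f"unknown species block {name!r}")
            if df.empty:
                raise ValueError(f"block {name!r} is empty")
            if name not in self.normalizers:
                self.normalizers[name] = _default_normalizer(name, df)
            norm = np.asarray(self.normalizers[name], dtype=float)
            if np.any(norm <= 0):
                raise ValueError(f"normalization constants for {name!r} must be > 0")
            self.normalizers[name] = norm

    @property
    def omega(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.blocks.items()}

    @classmethod
    def from_dataset(cls, ds: ExperimentalDataset, species: tuple[str, ...]) -> "CostSpec":
        return cls(blocks={name: ds.block(name) for name in species})


def _default_normalizer(name: str, df: pd.DataFrame) -> np.ndarray:
    """Per-row nondimensionalisation reference for one block."""
    if name == "oxygen":
        # ambient partial pressure of the condition
        return df["ambient_percent"].to_numpy() * MMHG_PER_PERCENT
    if name == "glucose":
        from .fv_solver import INITIAL_GLUCOSE_MEDIUM_MM

        return np.full(len(df), INITIAL_GLUCOSE_MEDIUM_MM)
    if name == "viability":
        return np.ones(len(df))  # already n/n0
    if name == "vegf":
        # initial VEGF is zero, so scale by the block's maximum observation
        vmax = float(df["value_pg_ml"].max())
        return np.full(len(df), vmax if vmax > 0 else 1.0)
    raise ValueError(name)


_MERGE_KEYS = {
    "oxygen": ["ambient_percent", "n0_per_ml", "time_h"],
    "glucose": ["ambient_percent", "n0_per_ml"],
    "viability": ["ambient_percent", "n0_per_ml"],
    "vegf": ["ambient_percent", "n0_per_ml"],
}


def make_forward(
    design: StudyDesign | None = None,
    geom=None,
    settings: SolverSettings | None = None,
    species: tuple[str, ...] = BLOCK_NAMES,
):
    """Forward closure: ParameterSet -> predicted observation blocks.

    Each call runs the solver once per unique experimental condition (the 12
    ambient x density pairs cover every block), so one cost evaluation costs
    at most 12 forward simulations.
    """
    design = StudyDesign() if design is None else design

    def forward(params: ParameterSet) -> dict[str, pd.DataFrame]:
        return predict_blocks(params, design, geom, settings, species=species)

    return forward


def cost(params: ParameterSet, spec: CostSpec, forward) -> float:
    """L1 calibration cost J at one parameter set (+inf on solver failure)."""
    try:
        preds = forward(params)
    except Exception as exc:  # noqa: BLE001 - any forward failure is a bad region
        logger.warning("forward model failed (%r); assigning cost +inf", exc)
        return float("inf")
    total = 0.0
    for name, obs in spec.blocks.items():
        keys = _MERGE_KEYS[name]
        col = _BLOCK_VALUE[name]
        merged = obs.merge(preds[name], on=keys, how="left", suffixes=("", "_pred"))
        pred = merged[f"{col}_pred"].to_numpy()
        if np.any(~np.isfinite(pred)):
            raise ValueError(
                f"predictions missing for some {name} observations; "
                "check the study design matches the dataset conditions"
            )
        resid = np.abs(pred - obs[col].to_numpy()) / spec.normalizers[name]
        total += float(resid.mean())
    return total


# ---------------------------------------------------------------------------
# Particle swarm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwarmConfig:
    """Global-best swarm settings.

    ``c1`` weights the pull toward each particle's personal best
    (individual behaviour), ``c2`` toward the global best (collective
    behaviour), ``w`` the velocity memory.  ``bounds`` is a (k, 2) array in
    the search space (log10 for wide-ranged parameters).
    """

    n_particles: int
    n_iters: int
    bounds: np.ndarray
    c1: float = 2.0
    c2: float = 2.0
    w: float = 0.7
    seed: int | None = None
    early_stop: bool = True
    tol_rel: float = 1e-6
    patience: int = 50
    velocity_clamp: float | None = 0.5  # max |v| as a fraction of the range

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.c1 <= 0 or self.c2 <= 0 or self.w <= 0:
            raise ValueError("acceleration and inertia coefficients must be > 0")
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or not np.all(np.isfinite(b)):
            raise ValueError("bounds must be a finite (k, 2) array")
        object.__setattr__(self, "bounds", b)


@dataclass
class CalibrationResult:
    """Outcome of one swarm run."""

    best_x: np.ndarray
    best_cost: float
    cost_trace: np.ndarray      # global best per iteration (nonincreasing)
    n_evaluations: int
    converged: str              # 'max_iters' | 'plateau'


def pso_minimize(cost_fn, config: SwarmConfig) -> CalibrationResult:
    """Global-best particle swarm with inertia and bound clipping.

    Velocity update ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``;
    positions are clipped to the bounds with the velocity zeroed on clipped
    coordinates.  Each iteration evaluates every particle, so a full run
    performs exactly ``n_particles * n_iters`` cost evaluations (fewer only
    if the plateau stop fires).  Bitwise reproducible under ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    k = lo.size
    n = config.n_particles
    x = lo + (hi - lo) * rng.random((n, k))
    v = np.zeros((n, k))
    pbest = x.copy()
    pbest_cost = np.full(n, np.inf)
    gbest = x[0].copy()
    gbest_cost = np.inf
    trace = []
    n_evals = 0
    reason = "max_iters"

    for it in range(config.n_iters):
        costs = np.array([cost_fn(xi) for xi in x], dtype=float)
        n_evals += n
        if it == 0 and not np.any(np.isfinite(costs)):
            raise RuntimeError("cost is non-finite at every initial particle")
        improved = costs < pbest_cost
        pbest[improved] = x[improved]
        pbest_cost[improved] = costs[improved]
        i_best = int(np.argmin(pbest_cost))
        if pbest_cost[i_best] < gbest_cost:
            gbest_cost = float(pbest_cost[i_best])
            gbest = pbest[i_best].copy()
        trace.append(gbest_cost)

        if config.early_stop and it >= config.patience:
            past = trace[-config.patience - 1]
            denom = abs(past) if past != 0 else 1.0
            if (past - gbest_cost) / denom < config.tol_rel:
                reason = "plateau"
                break

        if it < config.n_iters - 1:
            r1 = rng.random((n, k))
            r2 = rng.random((n, k))
            v = config.w * v + config.c1 * r1 * (pbest - x) + config.c2 * r2 * (gbest - x)
            if config.velocity_clamp is not None:
                vmax = config.velocity_clamp * (hi - lo)
                np.clip(v, -vmax, vmax, out=v)
            x = x + v
            clipped = (x < lo) | (x > hi)
            np.clip(x, lo, hi, out=x)
            v[clipped] = 0.0

    return CalibrationResult(
        best_x=gbest,
        best_cost=gbest_cost,
        cost_trace=np.asarray(trace),
        n_evaluations=n_evals,
        converged=reason,
    )


# ---------------------------------------------------------------------------
# Search-space transforms
# ---------------------------------------------------------------------------


def _search_bounds(names, bounds=None) -> np.ndarray:
    bounds = PARAMETER_BOUNDS if bounds is None else bounds
    out = []
    for name in names:
        lo, hi = bounds[name]
        if name in LOG_SCALE_PARAMETERS:
            out.append((np.log10(lo), np.log10(hi)))
        else:
            out.append((lo, hi))
    return np.asarray(out)


def _from_search(theta: np.ndarray, names) -> dict[str, float]:
    return {
        name: float(10**t if name in LOG_SCALE_PARAMETERS else t)
        for name, t in zip(names, theta)
    }


def _to_search(values: dict[str, float], names) -> np.ndarray:
    return np.array(
        [np.log10(values[n]) if n in LOG_SCALE_PARAMETERS else values[n] for n in names]
    )


# ---------------------------------------------------------------------------
# Two-step calibration
# ---------------------------------------------------------------------------


@dataclass
class TwoStepResult:
    params: ParameterSet
    step1: CalibrationResult | None
    step2: CalibrationResult | None

    def report(self) -> dict:
        """JSON-serialisable calibration report."""
        out = {"best_parameters": self.params.free_values()}
        for label, res in (("step1", self.step1), ("step2", self.step2)):
            out[label] = None if res is None else {
                "best_cost": res.best_cost,
                "n_evaluations": res.n_evaluations,
                "converged": res.converged,
            }
        return out


def _swarm_defaults(step: int) -> dict:
    # step 1: w=0.6; step 2: w=0.7 (same acceleration coefficients)
    return {"c1": 2.0, "c2": 0.2, "w": 0.6 if step == 1 else 0.7}


def calibrate_two_step(
    dataset: ExperimentalDataset,
    base_params: ParameterSet,
    n_particles: int = 20,
    n_iters: int = 1250,
    seed: int | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    design: StudyDesign | None = None,
    geom=None,
    settings: SolverSettings | None = None,
    swarm_kwargs: dict | None = None,
) -> TwoStepResult:
    """Sequential two-step swarm fit of the 16 calibrated constants.

    ``base_params`` supplies the nominal values of the fixed parameters (and
    of any step's parameters when that step is skipped for lack of data).
    Step 1 must succeed before step 2 runs; a step-1 failure propagates.
    """
    swarm_kwargs = swarm_kwargs or {}
    if bounds is None:
        bounds = calibration_bounds(base_params)
    step1_species = tuple(
        s for s in ("oxygen", "glucose", "viability") if not dataset.block(s).empty
    )
    current = base_params
    step1_res = None
    if step1_species:
        spec1 = CostSpec.from_dataset(dataset, step1_species)
        fwd1 = make_forward(design, geom, settings, species=step1_species)

        def cost1(theta: np.ndarray) -> float:
            p = current.replace(**_from_search(theta, STEP1_PARAMETERS))
            return cost(p, spec1, fwd1)

        cfg1 = SwarmConfig(
            n_particles=n_particles, n_iters=n_iters,
            bounds=_search_bounds(STEP1_PARAMETERS, bounds),
            seed=seed, **(_swarm_defaults(1) | swarm_kwargs),
        )
        step1_res = pso_minimize(cost1, cfg1)
        current = current.replace(**_from_search(step1_res.best_x, STEP1_PARAMETERS))
    else:
        warnings.warn(
            "no oxygen/glucose/viability observations: step 1 skipped; "
            "using provided non-VEGF parameters"
        )

    step2_res = None
    if not dataset.block("vegf").empty:
        spec2 = CostSpec.from_dataset(dataset, ("vegf",))
        fwd2 = make_forward(design, geom, settings, species=("vegf",))

        def cost2(theta: np.ndarray) -> float:
            p = current.replace(**_from_search(theta, STEP2_PARAMETERS))
            return cost(p, spec2, fwd2)

        cfg2 = SwarmConfig(
            n_particles=n_particles, n_iters=n_iters,
            bounds=_search_bounds(STEP2_PARAMETERS, bounds),
            seed=None if seed is None else seed + 1,
            **(_swarm_defaults(2) | swarm_kwargs),
        )
        step2_res = pso_minimize(cost2, cfg2)
        current = current.replace(**_from_search(step2_res.best_x, STEP2_PARAMETERS))

    return TwoStepResult(params=current, step1=step1_res, step2=step2_res)


def calibration_spread(
    dataset: ExperimentalDataset,
    base_params: ParameterSet,
    seeds: tuple[int, ...],
    **kwargs,
) -> pd.DataFrame:
    """Repeat the two-step calibration across seeds and tabulate the spread.

    One row per seed with the fitted values; summary rows give the mean,
    standard deviation and relative spread per parameter — the multi-start
    check that parameter variability, not the optimiser, limits the fit.
    """
    rows = []
    for s in seeds:
        res = calibrate_two_step(dataset, base_params, seed=s, **kwargs)
        rows.append({"seed": s, **res.params.free_values()})
    df = pd.DataFrame(rows).set_index("seed")
    summary = pd.DataFrame(
        {"mean": df.mean(), "std": df.std(ddof=1)}
    )
    summary["rel_spread"] = summary["std"] / summary["mean"].abs()
    df.attrs["summary"] = summary
    return df
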