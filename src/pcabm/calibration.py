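"""Particle-swarm calibration of simulator parameters to growth curves.

The free parameters of the stochastic simulator are fitted by global-best
particle swarm optimization (PSO) against relative growth curves, with the
mean squared error between the replicate-mean data curve and the average of
several simulated curves as cost.  The full staged protocol fits, in order:
tumor proliferation in the androgen-stimulated condition (including the
division capacity, assumed hormone-independent), tumor proliferation in the
deprived condition, fibroblast turnover (one condition, copied to the
other), M1 then M2 macrophage killing (plus the M2 growth bonus), optional
no-fibroblast refits, and finally the resistant-cell proliferation
parameters.  Each stage is fitted per biological replicate with many PSO
restarts; the across-replicate median of per-replicate medians is frozen
and fed to the next stage.

Integer capacities are searched on a continuous scale and rounded at
evaluation time, which lets a plain continuous PSO handle the mixed
discrete/continuous search space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet, get_preset
from .scenarios import build_scenario, relative_growth
from .simulator import ScenarioConfig, run_simulation
from .synthetic import GrowthDataset

__all__ = [
    "PSOConfig",
    "FitSpec",
    "FitResult",
    "mse_cost",
    "evaluate_candidate",
    "pso_minimize",
    "run_pso",
    "staged_fit",
    "DEFAULT_BOUNDS",
    "STAGES",
]

#: Parameters rounded to the nearest integer at evaluation time.
INTEGER_PARAMS = frozenset(
    {"TUpmax", "TUpmaxres", "M1kmax", "M2kmax", "Fpmax",
     "M1speed", "M2speed", "M1engagementDuration", "M2engagementDuration"})

#: Default search bounds per parameter (probabilities, the M2 growth bonus,
#: and division/kill capacities).
DEFAULT_BOUNDS: dict[str, tuple] = {
    "TUpprol": (0.0, 0.5), "TUpdeath": (0.0, 0.5),
    "TUpprolres": (0.0, 0.5), "TUpres": (0.0, 0.5),
    "M1pkill": (0.0, 0.5), "M2pkill": (0.0, 0.5),
    "Fpprol": (0.0, 0.5), "Fpdeath": (0.0, 0.5),
    "M2TUadd": (0.0, 0.3),
    "TUpmax": (1.0, 20.0), "M1kmax": (1.0, 20.0), "M2kmax": (1.0, 20.0),
    "Fpmax": (1.0, 20.0), "TUpmaxres": (1.0, 60.0),
}


@dataclass(frozen=True)
class PSOConfig:
    """Hyperparameters of the global-best PSO.

    Constriction-style defaults (inertia 0.729, cognitive = social =
    1.49445); velocities are clamped to ``velocity_clamp`` times each
    dimension's range and positions reflect at the bounds.
    """

    swarm_size: int = 20
    iterations: int = 60
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    velocity_clamp: float = 0.5
    restarts: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass(frozen=True)
class FitSpec:
    """What to fit: free parameters with bounds, everything else frozen.

    ``free_params`` maps parameter names to (lower, upper) bounds;
    ``fixed_params`` supplies every non-fitted value.  ``n_sim_rep``
    simulations (distinct derived seeds) are averaged per cost evaluation.
    """

    free_params: dict                 # name -> (lo, hi)
    fixed_params: ParameterSet
    scenario: ScenarioConfig
    target_kind: str = "tumor_total"
    n_sim_rep: int = 3
    t0_hours: float = 24.0

    def __post_init__(self):
        for name, (lo, hi) in self.free_params.items():
            if not np.isfinite(lo) or not np.isfinite(hi) or not lo < hi:
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")
            if name not in INTEGER_PARAMS and name in \
                    ParameterSet._PROBABILITIES and (lo < 0 or hi > 1):
                raise ValueError(f"probability {name} bounds outside [0, 1]")
        if set(self.free_params) & {f.name for f in
                                    dataclasses.fields(ParameterSet)} \
                != set(self.free_params):
            unknown = set(self.free_params) - \
                {f.name for f in dataclasses.fields(ParameterSet)}
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
        if not isinstance(self.fixed_params, ParameterSet):
            raise ValueError("fixed_params must be a ParameterSet")

    @property
    def names(self) -> list:
        return list(self.free_params)

    def build_params(self, vector: np.ndarray) -> ParameterSet:
        """ParameterSet with the candidate vector substituted (ints rounded)."""
        changes = {}
        for name, v in zip(self.names, vector):
            changes[name] = int(round(v)) if name in INTEGER_PARAMS \
                else float(v)
        return self.fixed_params.replace(**changes)


@dataclass
class FitResult:
    """Per-restart PSO optima and their robust aggregate.

    ``per_restart`` has one row per (bio_rep, restart) with the optimized
    parameter values, final cost, and a ``converged`` flag (see
    :func:`converged_restart_mask`); ``median``/``iqr`` are per-parameter
    across converged restarts (for multi-replicate fits the median of
    per-replicate medians, the value frozen and fed forward);
    ``cost_at_median`` is the cost of the median parameter vector on the
    pooled replicate-mean curve.
    """

    names: list
    per_restart: pd.DataFrame
    median: dict
    iqr: dict
    cost_at_median: float

    def median_vector(self) -> np.ndarray:
        return np.array([self.median[n] for n in self.names])

    def summary(self) -> str:
        lines = [f"{'parameter':<14}{'median':>12}{'IQR':>12}"]
        for n in self.names:
            lines.append(f"{n:<14}{self.median[n]:>12.5g}"
                         f"{self.iqr[n]:>12.5g}")
        n_conv = int(self.per_restart["converged"].sum()) \
            if "converged" in self.per_restart else len(self.per_restart)
        lines.append(f"restarts: {len(self.per_restart)} "
                     f"({n_conv} converged)   "
                     f"cost at median: {self.cost_at_median:.5g}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
def mse_cost(model_curve, data_curve) -> float:
    """Mean squared error between two relative growth curves.

    Curves are (times, values) pairs or objects with ``times``/``values``.
    Data times are matched to the nearest model time; a mismatch larger
    than half the model's time step is an error, as is an empty overlap.
    """
    mt, mv = _as_curve(model_curve)
    dt, dv = _as_curve(data_curve)
    if len(mt) == 0 or len(dt) == 0:
        raise ValueError("empty curve")
    step = np.min(np.diff(mt)) if len(mt) > 1 else np.inf
    idx = np.searchsorted(mt, dt)
    idx = np.clip(idx, 0, len(mt) - 1)
    left = np.clip(idx - 1, 0, len(mt) - 1)
    use_left = np.abs(mt[left] - dt) < np.abs(mt[idx] - dt)
    idx = np.where(use_left, left, idx)
    mism = np.abs(mt[idx] - dt)
    if np.any(mism > step / 2 + 1e-9):
        bad = dt[np.argmax(mism)]
        raise ValueError(
            f"data time {bad} h is more than half a time step from any "
            "model time")
    return float(np.mean((mv[idx] - dv) ** 2))


def _as_curve(c) -> tuple:
    if hasattr(c, "times"):
        return np.asarray(c.times, float), np.asarray(c.values, float)
    t, v = c
    return np.asarray(t, float), np.asarray(v, float)


def evaluate_candidate(vector: np.ndarray, fit_spec: FitSpec,
                       data_curve, seed: int = 0) -> float:
    """Cost of one candidate: average of ``n_sim_rep`` simulated relative
    curves (distinct derived seeds) vs. the data curve, as MSE.

    Deterministic given (vector, spec, data, seed).
    """
    params = fit_spec.build_params(np.asarray(vector, float))
    dt, dv = _as_curve(data_curve)
    acc = None
    times = None
    for r in range(fit_spec.n_sim_rep):
        run_seed = int(np.random.SeedSequence([int(seed), r])
                       .generate_state(1)[0] % 2**31)
        traj = run_simulation(fit_spec.scenario, params=params,
                              seed=run_seed)
        curve = relative_growth(traj, kind=fit_spec.target_kind,
                                t0_hours=fit_spec.t0_hours)
        acc = curve.values if acc is None else acc + curve.values
        times = curve.times
    mean_curve = (times, acc / fit_spec.n_sim_rep)
    return mse_cost(mean_curve, (dt, dv))


# ----------------------------------------------------------------------
def _rep_token(b) -> int:
    """Stable non-negative integer token for a replicate id."""
    try:
        return int(b) & 0x7FFFFFFF
    except (TypeError, ValueError):
        import zlib
        return zlib.crc32(str(b).encode())


def pso_minimize(cost_fn, bounds: np.ndarray, config: PSOConfig,
                 seed: int = 0) -> tuple:
    """Global-best PSO over a box; returns (x_best, f_best, best_history).

    ``cost_fn(x, eval_seed)`` is called with a per-iteration evaluation seed
    shared by all particles (common random numbers for stochastic costs).
    Velocities are clamped per dimension, positions reflect at the bounds,
    and the returned best-so-far history is non-increasing.
    """
    lo = bounds[:, 0]
    hi = bounds[:, 1]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    d = len(lo)
    span = hi - lo
    vmax = config.velocity_clamp * span
    X = lo + span * rng.uniform(size=(config.swarm_size, d))
    V = vmax * rng.uniform(-1, 1, size=(config.swarm_size, d))

    def eval_seed(it):
        return int(np.random.SeedSequence([int(seed), 1000 + it])
                   .generate_state(1)[0] % 2**31)

    costs = np.array([cost_fn(x, eval_seed(0)) for x in X])
    pbest = X.copy()
    pcost = costs.copy()
    g = int(np.argmin(pcost))
    gbest, gcost = pbest[g].copy(), float(pcost[g])
    history = [gcost]
    for it in range(1, config.iterations + 1):
        r1 = rng.uniform(size=(config.swarm_size, d))
        r2 = rng.uniform(size=(config.swarm_size, d))
        V = (config.inertia * V
             + config.cognitive * r1 * (pbest - X)
             + config.social * r2 * (gbest - X))
        V = np.clip(V, -vmax, vmax)
        X = X + V
        # reflect at the bounds
        over_lo = X < lo
        X = np.where(over_lo, 2 * lo - X, X)
        V = np.where(over_lo, -V, V)
        over_hi = X > hi
        X = np.where(over_hi, 2 * hi - X, X)
        V = np.where(over_hi, -V, V)
        X = np.clip(X, lo, hi)  # guard against double reflection
        s = eval_seed(it)
        costs = np.array([cost_fn(x, s) for x in X])
        better = costs < pcost
        pbest[better] = X[better]
        pcost[better] = costs[better]
        g = int(np.argmin(pcost))
        if pcost[g] < gcost:
            gbest, gcost = pbest[g].copy(), float(pcost[g])
        history.append(gcost)
    return gbest, gcost, np.array(history)


def converged_restart_mask(costs, factor: float = 100.0) -> np.ndarray:
    """Flag restarts that converged to the best basin found.

    The restart median assumes restarts are noisy draws around one optimum.
    When the cost surface is multimodal, restarts trapped in a spurious
    basin report costs orders of magnitude above the best restart, while
    evaluation noise only perturbs costs by factors of a few; the median
    over *all* restarts can then land in the wrong basin.  Restarts whose
    cost exceeds ``factor`` times the best restart's cost are therefore
    excluded from aggregation (they remain in the per-restart table,
    flagged ``converged=False``).
    """
    c = np.asarray(costs, dtype=float)
    return c <= factor * max(float(c.min()), 1e-9)


def run_pso(fit_spec: FitSpec, dataset, pso_config: PSOConfig) -> FitResult:
    """Fit the free parameters to a dataset with restarted PSO.

    ``dataset`` is a :class:`~pcabm.synthetic.GrowthDataset` (fitted per
    biological replicate against the technical-replicate mean curve) or a
    bare (times, values) curve.  Returns per-restart optima plus the
    median/IQR aggregate over the converged restarts (see
    :func:`converged_restart_mask`).
    """
    names = fit_spec.names
    bounds = np.array([fit_spec.free_params[n] for n in names], float)
    if isinstance(dataset, GrowthDataset):
        reps = dataset.bio_reps()
        curves = {b: dataset.replicate_mean_curve(b) for b in reps}
        pooled = dataset.replicate_mean_curve()
    else:
        curves = {1: _as_curve(dataset)}
        pooled = _as_curve(dataset)

    rows = []
    failures = []
    rep_medians = []
    for b, curve in curves.items():
        rep_rows = []
        for r in range(pso_config.restarts):
            restart_seed = int(np.random.SeedSequence(
                [pso_config.seed, _rep_token(b), r])
                .generate_state(1)[0] % 2**31)
            try:
                x, f, _ = pso_minimize(
                    lambda v, s: evaluate_candidate(v, fit_spec, curve, s),
                    bounds, pso_config, seed=restart_seed)
            except Exception as e:  # pragma: no cover - defensive
                failures.append(e)
                continue
            row = {"bio_rep": b, "restart": r, "cost": f}
            row.update(dict(zip(names, x)))
            rep_rows.append(row)
        if rep_rows:
            rep_df = pd.DataFrame(rep_rows)
            rep_df["converged"] = converged_restart_mask(rep_df["cost"])
            rep_medians.append(rep_df.loc[rep_df["converged"], names].median())
            rows.extend(rep_df.to_dict("records"))
    if not rows:
        raise RuntimeError(f"all PSO restarts failed: {failures[:1]}")
    per_restart = pd.DataFrame(rows)
    med_across_reps = pd.concat(rep_medians, axis=1).T.median()
    median = {}
    for n in names:
        v = float(med_across_reps[n])
        median[n] = int(round(v)) if n in INTEGER_PARAMS else v
    q = per_restart.loc[per_restart["converged"], names].quantile([0.25, 0.75])
    iqr = {n: float(q.loc[0.75, n] - q.loc[0.25, n]) for n in names}
    cost_at_median = evaluate_candidate(
        np.array([median[n] for n in names], float), fit_spec, pooled,
        seed=pso_config.seed)
    return FitResult(names=names, per_restart=per_restart, median=median,
                     iqr=iqr, cost_at_median=cost_at_median)


# ----------------------------------------------------------------------
# Staged protocol.  Each stage: (dataset key, scenario base name, condition,
# target population kind, free parameter names).  Frozen values flow forward
# through the evolving per-condition ParameterSet.

STAGES = (
    "tumor_mono_R1881", "tumor_mono_DMSO", "fibroblast_R1881",
    "tu_f_m1_R1881", "tu_f_m1_DMSO", "tu_f_m2_R1881", "tu_f_m2_DMSO",
    "tu_m1_DMSO_kill", "tu_m1_DMSO_prol", "tu_m2_DMSO_kill",
    "resistant_DMSO",
)


def _bounds_for(names, bounds_override=None):
    out = {}
    for n in names:
        if bounds_override and n in bounds_override:
            out[n] = tuple(bounds_override[n])
        else:
            out[n] = DEFAULT_BOUNDS[n]
    return out


def staged_fit(datasets: dict, pso_config: PSOConfig,
               base_params: dict | None = None,
               stages: tuple | None = None,
               n_sim_rep: int = 3,
               base_count: int = 1000,
               lattice=None,
               bounds: dict | None = None,
               fit_fpmax: bool = False) -> tuple:
    """Run the staged calibration protocol over the provided datasets.

    ``datasets`` maps stage keys (see :data:`STAGES`; the optional
    no-fibroblast refits share one dataset under ``tu_m1_DMSO`` /
    ``tu_m2_DMSO``) to :class:`GrowthDataset` objects.  Only stages whose
    data is present are run, in protocol order; a stage whose prerequisite
    data is missing raises a ``KeyError`` naming the stage.  Returns
    ``(params_by_condition, fit_results_by_stage)``.

    Protocol logic: the tumor division capacity is fitted only under
    androgen stimulation and frozen elsewhere; fibroblast parameters are
    fitted in one condition and copied to the other; the M1 kill capacity
    is fitted under stimulation only and reused for M2; the M2 growth
    bonus is fitted alongside the M2 kill probability.
    """
    if stages is None:
        stages = tuple(k for k in STAGES
                       if _stage_dataset_key(k) in datasets)
    params = dict(base_params) if base_params else \
        {"DMSO": get_preset("DMSO"), "R1881": get_preset("R1881")}
    results: dict[str, FitResult] = {}

    for stage in stages:
        key = _stage_dataset_key(stage)
        if key not in datasets:
            raise KeyError(f"stage {stage!r} requires dataset {key!r}")
        cond = "R1881" if stage.endswith("R1881") else "DMSO"
        scen_base, target, free = _stage_plan(stage, params, results)
        scenario = build_scenario(f"{scen_base}_{cond}",
                                  base_count=base_count, lattice=lattice)
        spec = FitSpec(free_params=_bounds_for(free, bounds),
                       fixed_params=params[cond], scenario=scenario,
                       target_kind=target, n_sim_rep=n_sim_rep)
        res = run_pso(spec, datasets[key], pso_config)
        results[stage] = res
        params[cond] = spec.build_params(res.median_vector())
        # cross-condition freezes
        if stage == "tumor_mono_R1881":
            # division capacity assumed hormone-independent
            params["DMSO"] = params["DMSO"].replace(
                TUpmax=params["R1881"].TUpmax)
        elif stage == "fibroblast_R1881":
            # fibroblasts grow alike in both conditions
            upd = {n: getattr(params["R1881"], n) for n in res.names}
            params["DMSO"] = params["DMSO"].replace(**upd)
        elif stage == "tu_f_m1_R1881":
            # M2 kill capacity reuses the fitted M1 capacity
            for c in ("DMSO", "R1881"):
                params[c] = params[c].replace(
                    M1kmax=params["R1881"].M1kmax,
                    M2kmax=params["R1881"].M1kmax)
    return params, results


def _stage_dataset_key(stage: str) -> str:
    if stage in ("tu_m1_DMSO_kill", "tu_m1_DMSO_prol"):
        return "tu_m1_DMSO"
    if stage == "tu_m2_DMSO_kill":
        return "tu_m2_DMSO"
    return stage


def _stage_plan(stage: str, params: dict, results: dict) -> tuple:
    """(scenario base name, target kind, free parameter names) per stage."""
    if stage == "tumor_mono_R1881":
        return "LNCaP", "tumor_total", ["TUpprol", "TUpmax"]
    if stage == "tumor_mono_DMSO":
        if "tumor_mono_R1881" not in results:
            raise KeyError(
                "stage 'tumor_mono_DMSO' requires the frozen division "
                "capacity from stage 'tumor_mono_R1881'")
        return "LNCaP", "tumor_total", ["TUpprol"]
    if stage == "fibroblast_R1881":
        free = ["Fpprol", "Fpdeath"]
        return "fibroblast", "fibroblast", free
    if stage == "tu_f_m1_R1881":
        return "LNCaP_F_M1_411", "tumor_total", ["M1pkill", "M1kmax"]
    if stage == "tu_f_m1_DMSO":
        return "LNCaP_F_M1_411", "tumor_total", ["M1pkill"]
    if stage in ("tu_f_m2_R1881", "tu_f_m2_DMSO"):
        return "LNCaP_F_M2_411", "tumor_total", ["M2pkill", "M2TUadd"]
    if stage == "tu_m1_DMSO_kill":
        # macrophage killing refit with tumor proliferation frozen at the
        # vehicle value (the lower-cost scheme)
        return "LNCaP_M1_41", "tumor_total", ["M1pkill"]
    if stage == "tu_m1_DMSO_prol":
        # alternative scheme: proliferation refit with killing frozen
        return "LNCaP_M1_41", "tumor_total", ["TUpprol"]
    if stage == "tu_m2_DMSO_kill":
        return "LNCaP_M2_41", "tumor_total", ["M2pkill"]
    if stage == "resistant_DMSO":
        return "LNCaP_abl", "tumor_total", ["TUpprolres", "TUpmaxres"]
    raise KeyError(f"unknown stage {stage!r}; stages: {STAGES}")
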