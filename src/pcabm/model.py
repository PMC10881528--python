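"""Model/Results façade for calibrating the simulator to growth data.

Follows the convention of statistical modelling packages: a model object is
built from data plus a specification, ``fit()`` runs the estimation and
returns a results object carrying estimates, their spread across restarts,
diagnostics and a ``summary()`` table; simulation hangs off both objects.

Two levels are provided:

* :class:`GrowthCurveModel` — fit a chosen set of free parameters of one
  scenario against one growth dataset (single-stage PSO fit).
* :class:`StagedCalibration` — the full staged protocol across scenarios
  and hormone conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (DEFAULT_BOUNDS, FitResult, FitSpec, PSOConfig,
                          run_pso, staged_fit)
from .params import ParameterSet, get_preset
from .scenarios import relative_growth
from .simulator import ScenarioConfig, run_simulation
from .synthetic import GrowthDataset

__all__ = ["GrowthCurveModel", "GrowthCurveResults", "StagedCalibration",
           "StagedCalibrationResults"]


class GrowthCurveModel:
    """Calibrate simulator parameters against one growth dataset.

    Parameters
    ----------
    data : GrowthDataset or pandas.DataFrame
        Long-format relative growth curves (canonical schema).
    scenario : ScenarioConfig
        The culture the data describe (seeding, condition, duration).
    free_params : dict or list
        Parameter names to fit; a dict supplies (lower, upper) bounds,
        a list uses the package defaults.
    fixed_params : ParameterSet, optional
        Values for everything not fitted (default: the scenario's
        hormone-condition preset).
    target_kind : str
        Which population the data track (``tumor_total`` or
        ``fibroblast``).
    n_sim_rep : int
        Simulations averaged per cost evaluation.
    """

    def __init__(self, data, scenario: ScenarioConfig, free_params,
                 fixed_params: ParameterSet | None = None,
                 target_kind: str = "tumor_total", n_sim_rep: int = 3,
                 t0_hours: float = 24.0):
        if isinstance(data, pd.DataFrame):
            data = GrowthDataset(data)
        self.data = data
        self.scenario = scenario
        if not isinstance(free_params, dict):
            free_params = {n: DEFAULT_BOUNDS[n] for n in free_params}
        self.spec = FitSpec(
            free_params=free_params,
            fixed_params=fixed_params or scenario.params(),
            scenario=scenario, target_kind=target_kind,
            n_sim_rep=n_sim_rep, t0_hours=t0_hours)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scenario: ScenarioConfig,
                       free_params, **kwargs) -> "GrowthCurveModel":
        return cls(GrowthDataset(df), scenario, free_params, **kwargs)

    def fit(self, pso_config: PSOConfig | None = None,
            **pso_kwargs) -> "GrowthCurveResults":
        """Run restarted PSO and return the results object."""
        cfg = pso_config or PSOConfig(**pso_kwargs)
        res = run_pso(self.spec, self.data, cfg)
        return GrowthCurveResults(model=self, fit_result=res,
                                  pso_config=cfg)

    def simulate(self, params: ParameterSet | None = None, seed: int = 0,
                 **kwargs):
        """Simulate the model's scenario (at given or preset parameters)."""
        return run_simulation(self.scenario, params=params, seed=seed,
                              **kwargs)


@dataclass
class GrowthCurveResults:
    """Estimates and diagnostics of one PSO calibration."""

    model: GrowthCurveModel
    fit_result: FitResult
    pso_config: PSOConfig

    @property
    def params(self) -> ParameterSet:
        """Full parameter set with the fitted medians substituted."""
        return self.model.spec.build_params(self.fit_result.median_vector())

    @property
    def estimates(self) -> dict:
        return dict(self.fit_result.median)

    @property
    def iqr(self) -> dict:
        return dict(self.fit_result.iqr)

    @property
    def cost(self) -> float:
        return self.fit_result.cost_at_median

    @property
    def per_restart(self) -> pd.DataFrame:
        return self.fit_result.per_restart

    def predict(self, seed: int = 0, n_rep: int = 3):
        """Mean relative growth curve at the fitted parameters."""
        spec = self.model.spec
        acc, times = None, None
        for r in range(n_rep):
            s = int(np.random.SeedSequence([seed, r]).generate_state(1)[0]
                    % 2**31)
            traj = run_simulation(spec.scenario, params=self.params, seed=s)
            c = relative_growth(traj, kind=spec.target_kind,
                                t0_hours=spec.t0_hours)
            acc = c.values if acc is None else acc + c.values
            times = c.times
        return times, acc / n_rep

    def summary(self) -> str:
        m = self.model
        head = [
            "Growth-curve calibration (particle swarm)",
            "=" * 46,
            f"scenario:        {m.scenario.name}",
            f"condition:       {m.scenario.condition}",
            f"target:          {m.spec.target_kind}",
            f"observations:    {len(m.data)}",
            f"restarts:        {self.pso_config.restarts} "
            f"(swarm {self.pso_config.swarm_size}, "
            f"{self.pso_config.iterations} iterations)",
            "",
        ]
        return "\n".join(head) + self.fit_result.summary()


class StagedCalibration:
    """Full staged calibration protocol across scenarios and conditions.

    ``datasets`` maps stage keys (see :data:`pcabm.calibration.STAGES`)
    to growth datasets; only supplied stages are fitted, in protocol order.
    """

    def __init__(self, datasets: dict, n_sim_rep: int = 3,
                 base_count: int = 1000, lattice=None,
                 base_params: dict | None = None,
                 bounds: dict | None = None):
        self.datasets = dict(datasets)
        self.n_sim_rep = n_sim_rep
        self.base_count = base_count
        self.lattice = lattice
        self.base_params = base_params
        self.bounds = bounds

    def fit(self, pso_config: PSOConfig | None = None,
            stages: tuple | None = None,
            **pso_kwargs) -> "StagedCalibrationResults":
        cfg = pso_config or PSOConfig(**pso_kwargs)
        params, results = staged_fit(
            self.datasets, cfg, base_params=self.base_params,
            stages=stages, n_sim_rep=self.n_sim_rep,
            base_count=self.base_count, lattice=self.lattice,
            bounds=self.bounds)
        return StagedCalibrationResults(model=self, params_by_condition=params,
                                        stage_results=results,
                                        pso_config=cfg)


@dataclass
class StagedCalibrationResults:
    """Per-condition parameter sets and per-stage fit diagnostics."""

    model: StagedCalibration
    params_by_condition: dict
    stage_results: dict
    pso_config: PSOConfig

    def params(self, condition: str) -> ParameterSet:
        return self.params_by_condition[condition]

    def summary(self) -> str:
        lines = ["Staged calibration", "=" * 46]
        for stage, res in self.stage_results.items():
            lines.append(f"\n[{stage}]")
            lines.append(res.summary())
        return "\n".join(lines)
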