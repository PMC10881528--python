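"""Synthetic growth-curve datasets shaped like the calibration experiments.

The model is calibrated against live-cell-imaging growth curves: 7-day
co-cultures sampled every 4 hours, three biological replicates with six
technical replicates each, in two hormone conditions, with every series
normalized to its own 24-hour reading.  This module generates datasets with
exactly that structure, either from a smooth logistic stand-in (fast,
noise-controlled) or from the simulator itself (ground truth known, used for
parameter-recovery experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet
from .scenarios import relative_growth
from .simulator import ScenarioConfig, run_simulation

__all__ = [
    "GROWTH_SCHEMA",
    "GrowthDataset",
    "SyntheticSpec",
    "generate_logistic_dataset",
    "generate_simulated_dataset",
]

#: Required long-format columns, in canonical order.
GROWTH_SCHEMA = ("time_h", "condition", "bio_rep", "tech_rep",
                 "population", "relative_count")

VALID_CONDITIONS = ("DMSO", "R1881")


@dataclass
class GrowthDataset:
    """Long-format growth curves (one row per observation).

    Thin wrapper over a DataFrame with the canonical schema; extra columns
    are preserved.  ``relative_count`` is dimensionless (normalized to the
    series' own value at the normalization time, conventionally 24 h).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in GROWTH_SCHEMA if c not in self.df.columns]
        if missing:
            raise ValueError(f"growth dataset missing column(s): {missing}")
        if len(self.df) == 0:
            raise ValueError("growth dataset is empty")

    def __len__(self) -> int:
        return len(self.df)

    def conditions(self) -> list:
        return sorted(self.df["condition"].unique())

    def select(self, condition: str | None = None,
               population: str | None = None,
               bio_rep=None) -> "GrowthDataset":
        df = self.df
        if condition is not None:
            df = df[df["condition"] == condition]
        if population is not None:
            df = df[df["population"] == population]
        if bio_rep is not None:
            df = df[df["bio_rep"] == bio_rep]
        return GrowthDataset(df.reset_index(drop=True))

    def bio_reps(self) -> list:
        return sorted(self.df["bio_rep"].unique())

    def replicate_mean_curve(self, bio_rep=None) -> tuple:
        """(times_h, mean relative counts), technical replicates averaged.

        With ``bio_rep`` given, averages that biological replicate's
        technical replicates; otherwise averages everything.
        """
        df = self.df if bio_rep is None else \
            self.df[self.df["bio_rep"] == bio_rep]
        if len(df) == 0:
            raise ValueError(f"no rows for bio_rep={bio_rep!r}")
        g = df.groupby("time_h")["relative_count"].mean().sort_index()
        return g.index.to_numpy(float), g.to_numpy(float)


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and noise of a synthetic logistic growth dataset.

    The logistic mean curve is n(t) = K / (1 + ((K - n0)/n0) exp(-r t)) in
    arbitrary abundance units; per-observation noise is multiplicative
    log-normal; every series is renormalized to its 24-h point afterwards.
    ``rates`` maps each condition label to its growth rate r (per hour) —
    defaults emulate strong androgen-stimulated vs. slow deprived growth.
    """

    K: float = 25.0                  # carrying capacity (abundance units)
    n0: float = 1.0                  # initial abundance
    rates: dict = field(default_factory=lambda:
                        {"DMSO": 0.008, "R1881": 0.016})  # per hour
    noise_sd: float = 0.05           # log-normal sigma per observation
    n_bio: int = 3
    n_tech: int = 6
    t_max_h: float = 168.0
    dt_h: float = 4.0
    t0_h: float = 24.0               # normalization time
    population: str = "tumor"
    seed: int = 0

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("carrying capacity K must be > 0")
        if not (0 < self.n0 < self.K):
            raise ValueError("initial abundance n0 must satisfy 0 < n0 < K")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _logistic(t: np.ndarray, K: float, n0: float, r: float) -> np.ndarray:
    return K / (1.0 + ((K - n0) / n0) * np.exp(-r * t))


def generate_logistic_dataset(spec: SyntheticSpec) -> GrowthDataset:
    """Smooth logistic stand-in for imaging-derived growth curves.

    One series per (condition, biological replicate, technical replicate);
    observations carry independent multiplicative log-normal noise and each
    series is renormalized to its own value at ``spec.t0_h``.  Seeded and
    fully reproducible.
    """
    times = np.arange(0.0, spec.t_max_h + spec.dt_h / 2, spec.dt_h)
    i0 = int(np.argmin(np.abs(times - spec.t0_h)))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    rows = []
    for cond, r in spec.rates.items():
        mean = _logistic(times, spec.K, spec.n0, r)
        for b in range(1, spec.n_bio + 1):
            for tch in range(1, spec.n_tech + 1):
                noise = np.exp(rng.normal(0.0, spec.noise_sd, size=len(times))) \
                    if spec.noise_sd > 0 else np.ones(len(times))
                series = mean * noise
                series = series / series[i0]
                rows.append(pd.DataFrame({
                    "time_h": times, "condition": cond, "bio_rep": b,
                    "tech_rep": tch, "population": spec.population,
                    "relative_count": series,
                }))
    return GrowthDataset(pd.concat(rows, ignore_index=True))


def generate_simulated_dataset(params: ParameterSet,
                               scenario: ScenarioConfig,
                               n_bio: int = 3, n_tech: int = 6,
                               seed: int = 0,
                               population: str = "tumor",
                               kind: str = "tumor_total",
                               t0_hours: float = 24.0) -> GrowthDataset:
    """Ground-truth growth dataset: every technical replicate is one
    simulator run with its own derived seed, normalized at ``t0_hours``.

    The condition label is taken from the scenario.  Used for
    parameter-recovery experiments where the generating parameters are
    known exactly.
    """
    rows = []
    for b in range(1, n_bio + 1):
        for tch in range(1, n_tech + 1):
            run_seed = int(np.random.SeedSequence([seed, b, tch])
                           .generate_state(1)[0] % 2**31)
            traj = run_simulation(scenario, params=params, seed=run_seed)
            curve = relative_growth(traj, kind=kind, t0_hours=t0_hours)
            rows.append(pd.DataFrame({
                "time_h": curve.times, "condition": scenario.condition,
                "bio_rep": b, "tech_rep": tch, "population": population,
                "relative_count": curve.values,
            }))
    return GrowthDataset(pd.concat(rows, ignore_index=True))
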