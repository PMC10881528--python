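"""Named co-culture scenarios, growth-curve normalization, and reporting.

The scenario catalog mirrors the calibration experiments: LNCaP prostate
cancer cells alone or with fibroblasts (4:1, 1:1), with fibroblasts plus
M1- or M2-polarized macrophages (4:1:1), macrophage-dose variants
(M:TU:F at 1:4:1 and 1:1:1), tumor + macrophage cultures without
fibroblasts, and castration-resistance scenarios seeded with one resistant
cell per 100 sensitive cells.  Every scenario exists in both hormone
conditions (vehicle ``DMSO`` vs. androgen-stimulated ``R1881``).

Reporting helpers normalize trajectories to the 24-hour time point (the
convention of the live-cell-imaging data the model is calibrated to),
compute fold changes between parameter values, and quantify spatial
clustering of resistant cells with a nearest-neighbor index.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .params import ParameterSet
from .simulator import (KIND_CODES, LatticeConfig, ScenarioConfig,
                        Trajectory, run_simulation)

__all__ = [
    "GrowthCurve",
    "CATALOG",
    "scenario_names",
    "build_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "relative_growth",
    "fold_change",
    "fold_change_report",
    "nearest_neighbor_clustering",
    "clustering_permutation_pvalue",
    "mean_final_count",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Relative population size over time, normalized to one time point."""

    times: np.ndarray   # hours
    values: np.ndarray  # dimensionless, 1 at the normalization time
    kind: str = "tumor_total"

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# ----------------------------------------------------------------------
# Scenario catalog.  Ratios are expressed in the captions' listing order:
# tumor-led co-cultures read TU:F(:M), macrophage-dose scenarios read M:TU:F.
# Base entries map kind -> ratio weight relative to the tumor population.
_RESISTANT_SEED = 1.0 / 101.0  # one resistant per 100 sensitive cells

_BASE_CATALOG: dict[str, dict] = {
    # monocultures (calibration stages)
    "LNCaP": {"ratios": {"tumor": 1.0}},
    "LNCaP_abl": {"ratios": {"tumor": 1.0}, "resistant_fraction": 1.0},
    "fibroblast": {"ratios": {"fibroblast": 1.0}, "tumor_base": False},
    # tumor + fibroblast co-cultures
    "LNCaP_F_41": {"ratios": {"tumor": 1.0, "fibroblast": 0.25}},
    "LNCaP_F_11": {"ratios": {"tumor": 1.0, "fibroblast": 1.0}},
    # three-type co-cultures, TU:F:M = 4:1:1
    "LNCaP_F_M1_411": {"ratios": {"tumor": 1.0, "fibroblast": 0.25,
                                  "M1": 0.25}},
    "LNCaP_F_M2_411": {"ratios": {"tumor": 1.0, "fibroblast": 0.25,
                                  "M2": 0.25}},
    # tumor + macrophage only (no fibroblasts), 4:1 as in vitro
    "LNCaP_M1_41": {"ratios": {"tumor": 1.0, "M1": 0.25}},
    "LNCaP_M2_41": {"ratios": {"tumor": 1.0, "M2": 0.25}},
    # macrophage dose scenarios, M:TU:F
    "M1_TU_F_141": {"ratios": {"tumor": 1.0, "M1": 0.25,
                               "fibroblast": 0.25}},
    "M1_TU_F_111": {"ratios": {"tumor": 1.0, "M1": 1.0, "fibroblast": 1.0}},
    "M2_TU_F_141": {"ratios": {"tumor": 1.0, "M2": 0.25,
                               "fibroblast": 0.25}},
    "M2_TU_F_111": {"ratios": {"tumor": 1.0, "M2": 1.0, "fibroblast": 1.0}},
    # castration-resistance scenarios: rare resistant clone among sensitive
    "CRPC": {"ratios": {"tumor": 1.0}, "resistant_fraction": _RESISTANT_SEED},
    "CRPC_F_41": {"ratios": {"tumor": 1.0, "fibroblast": 0.25},
                  "resistant_fraction": _RESISTANT_SEED},
    "CRPC_F_11": {"ratios": {"tumor": 1.0, "fibroblast": 1.0},
                  "resistant_fraction": _RESISTANT_SEED},
    "CRPC_M1_TU_F_141": {"ratios": {"tumor": 1.0, "M1": 0.25,
                                    "fibroblast": 0.25},
                         "resistant_fraction": _RESISTANT_SEED},
    "CRPC_M1_TU_F_111": {"ratios": {"tumor": 1.0, "M1": 1.0,
                                    "fibroblast": 1.0},
                         "resistant_fraction": _RESISTANT_SEED},
    "CRPC_M2_TU_F_141": {"ratios": {"tumor": 1.0, "M2": 0.25,
                                    "fibroblast": 0.25},
                         "resistant_fraction": _RESISTANT_SEED},
    "CRPC_M2_TU_F_111": {"ratios": {"tumor": 1.0, "M2": 1.0,
                                    "fibroblast": 1.0},
                         "resistant_fraction": _RESISTANT_SEED},
}

CONDITIONS = ("DMSO", "R1881")

#: All registered scenario names ("<base>_<condition>").
CATALOG = tuple(f"{base}_{cond}"
                for base in _BASE_CATALOG for cond in CONDITIONS)

#: Default tumor seeding: 1,000 cells on the 125x125 grid (~6.4% occupancy);
#: the in vitro ratios scale the other populations from this base.
DEFAULT_BASE_COUNT = 1000


def scenario_names() -> list:
    return list(CATALOG)


def build_scenario(name: str, base_count: int = DEFAULT_BASE_COUNT,
                   ticks: int = 42,
                   lattice: LatticeConfig | None = None) -> ScenarioConfig:
    """Build a fully specified config for a registered scenario name.

    ``base_count`` is the tumor seeding count the ratio weights multiply
    (for the fibroblast monoculture it is the fibroblast count);
    ``ticks`` defaults to 42 (168 h of 4-h ticks, the 7-day assay length).
    """
    base = None
    cond = None
    for c in CONDITIONS:
        suffix = "_" + c
        if name.endswith(suffix) and name[: -len(suffix)] in _BASE_CATALOG:
            base, cond = name[: -len(suffix)], c
            break
    if base is None:
        raise KeyError(
            f"unknown scenario {name!r}; registered scenarios: "
            f"{', '.join(CATALOG)}"
        )
    entry = _BASE_CATALOG[base]
    counts = {k: int(round(w * base_count))
              for k, w in entry["ratios"].items()}
    return ScenarioConfig(
        name=name,
        lattice=lattice or LatticeConfig(),
        counts=counts,
        condition=cond,
        ticks=ticks,
        resistant_fraction=entry.get("resistant_fraction", 0.0),
    )


def scenario_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    lat = d.pop("lattice", None)
    lattice = LatticeConfig(**lat) if lat else LatticeConfig()
    return ScenarioConfig(lattice=lattice, **d)


# ----------------------------------------------------------------------
def relative_growth(trajectory: Trajectory, kind: str = "tumor_total",
                    t0_hours: float = 24.0) -> GrowthCurve:
    """Normalize a population's count series to its value at ``t0_hours``.

    Mirrors the normalization applied to the imaging data ("time point
    zero" at 24 h).  The count at the normalization tick must be positive.
    """
    times = trajectory.times_hours
    idx = int(np.argmin(np.abs(times - t0_hours)))
    if abs(times[idx] - t0_hours) > trajectory.tick_hours / 2:
        raise ValueError(
            f"t0 = {t0_hours} h does not correspond to a recorded tick "
            f"(nearest: {times[idx]} h)"
        )
    counts = trajectory.count_series(kind).astype(float)
    if counts[idx] <= 0:
        raise ValueError(
            f"count of {kind!r} at t0 = {t0_hours} h is zero; "
            "relative growth undefined"
        )
    return GrowthCurve(times=times, values=counts / counts[idx], kind=kind)


def fold_change(value_a: float, value_b: float) -> float:
    """Ratio value_a / value_b (value_b must be positive)."""
    if value_b <= 0:
        raise ValueError(f"denominator must be > 0, got {value_b!r}")
    return value_a / value_b


def fold_change_report(value_a: float, value_b: float) -> tuple:
    """(ratio, nearest-integer fold) for reporting."""
    r = fold_change(value_a, value_b)
    return r, int(round(r))


# ----------------------------------------------------------------------
def _positions_of(snapshot: np.ndarray, kind: str) -> np.ndarray:
    code = KIND_CODES[kind]
    return np.argwhere(snapshot == code)


def _mean_nn_distance(points: np.ndarray) -> float:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(d[:, 1].mean())


def _null_mean_nn(n: int, shape: tuple, n_null: int,
                  rng: np.random.Generator) -> float:
    """Monte Carlo mean nearest-neighbor distance under uniform
    collision-free placement of n points on an H x W lattice."""
    H, W = shape
    total = 0.0
    for _ in range(n_null):
        flat = rng.choice(H * W, size=n, replace=False)
        pts = np.column_stack([flat // W, flat % W])
        total += _mean_nn_distance(pts)
    return total / n_null


def nearest_neighbor_clustering(snapshot: np.ndarray, kind: str,
                                n_null: int = 199,
                                seed: int = 0) -> float:
    """Clark–Evans-style clustering index for one agent kind.

    Ratio of the observed mean nearest-neighbor distance to its expectation
    under uniform random (collision-free) placement of the same number of
    agents on the same grid, the latter estimated by Monte Carlo.  Values
    below 1 indicate spatial clustering, above 1 over-dispersion.

    Raises ``ValueError`` when fewer than two agents of the kind are
    present (the index is undefined).
    """
    pts = _positions_of(snapshot, kind)
    if len(pts) < 2:
        raise ValueError(
            f"clustering index undefined: {len(pts)} agent(s) of kind "
            f"{kind!r} in snapshot (need >= 2)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    expected = _null_mean_nn(len(pts), snapshot.shape, n_null, rng)
    return _mean_nn_distance(pts) / expected


def clustering_permutation_pvalue(snapshot: np.ndarray, kind: str,
                                  n_perm: int = 999,
                                  seed: int = 0) -> float:
    """One-sided permutation p-value for clustering (small mean NN distance).

    Compares the observed mean nearest-neighbor distance with ``n_perm``
    uniform random placements of the same count on the same grid.
    """
    pts = _positions_of(snapshot, kind)
    if len(pts) < 2:
        raise ValueError("need >= 2 agents for a permutation test")
    obs = _mean_nn_distance(pts)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    H, W = snapshot.shape
    hits = 0
    for _ in range(n_perm):
        flat = rng.choice(H * W, size=len(pts), replace=False)
        p = np.column_stack([flat // W, flat % W])
        if _mean_nn_distance(p) <= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def mean_final_count(config: ScenarioConfig, kind: str = "tumor_total",
                     n_seeds: int = 100, seed: int = 0,
                     params: ParameterSet | None = None) -> float:
    """Mean final population count over independent replicate simulations."""
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % 2**31
    finals = [run_simulation(config, params=params, seed=int(s))
              .count_series(kind)[-1] for s in seeds]
    return float(np.mean(finals))
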