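"""On-lattice stochastic simulator of the prostate tumor microenvironment.

Four agent types — androgen-sensitive tumor cells, castration-resistant
tumor cells, fibroblasts, and M1/M2-polarized macrophages — occupy a bounded
rectangular grid, one agent per cell (each grid cell sized like one tumor
cell).  Every 4-hour tick each agent resolves at most one stochastic action
(die, divide/kill, migrate, or idle), in the fixed phase order tumor →
fibroblast → M1 → M2.  Division and migration require a free Moore neighbor,
so populations compete for space; tumor cells carry a limited division
capacity and macrophages a limited kill capacity followed by a refractory
engagement period.

The heavy lifting is done by numba kernels in :mod:`pcabm._kernels`; this
module provides the user-facing dataclasses and the run loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .params import ParameterSet, get_preset

__all__ = [
    "KIND_CODES",
    "KIND_NAMES",
    "LatticeConfig",
    "ScenarioConfig",
    "SimulationState",
    "Trajectory",
    "moore_neighbors",
    "initialize_state",
    "effective_tumor_pprol",
    "advance_one_tick",
    "run_simulation",
    "resolve_tumor_action",
    "resolve_fibroblast_action",
    "resolve_macrophage_action",
]

#: Snapshot/state integer codes per agent kind (0 = empty grid cell).
KIND_CODES = {
    "tumor": 1,
    "tumor_resistant": 2,
    "fibroblast": 3,
    "M1": 4,
    "M2": 5,
}
KIND_NAMES = {v: k for k, v in KIND_CODES.items()}

DEFAULT_TICK_HOURS = 4.0


@dataclass(frozen=True)
class LatticeConfig:
    """Bounded rectangular grid; no wraparound (models a culture well)."""

    width: int = 125
    height: int = 125
    cell_area: float = 142.89  # µm², the footprint of one tumor cell

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully specified simulation scenario.

    ``counts`` maps kind names (``tumor``, ``tumor_resistant``,
    ``fibroblast``, ``M1``, ``M2``) to initial agent numbers; ``condition``
    selects the hormone-condition parameter preset unless explicit
    parameters are supplied to :func:`run_simulation`.
    """

    name: str = "custom"
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    counts: dict = field(default_factory=lambda: {"tumor": 1000})
    condition: str = "R1881"
    ticks: int = 42  # 168 h at 4-h ticks
    resistant_fraction: float = 0.0

    def __post_init__(self):
        if self.ticks < 1:
            raise ValueError("ticks must be >= 1")
        if not (0.0 <= self.resistant_fraction <= 1.0):
            raise ValueError("resistant_fraction must lie in [0, 1]")
        for kname, n in self.counts.items():
            if kname not in KIND_CODES:
                raise ValueError(f"unknown agent kind {kname!r}")
            if n < 0:
                raise ValueError(f"negative count for {kname!r}")
        if self.total_agents > self.lattice.n_cells:
            raise ValueError(
                f"{self.total_agents} agents exceed lattice capacity "
                f"{self.lattice.n_cells}"
            )

    @property
    def total_agents(self) -> int:
        return int(sum(self.counts.values()))

    def effective_counts(self) -> dict:
        """Counts with ``resistant_fraction`` of tumor cells made resistant."""
        counts = {k: int(v) for k, v in self.counts.items() if v > 0}
        if self.resistant_fraction > 0 and counts.get("tumor", 0) > 0:
            n_tu = counts["tumor"]
            n_res = int(round(self.resistant_fraction * n_tu))
            counts["tumor"] = n_tu - n_res
            counts["tumor_resistant"] = counts.get("tumor_resistant", 0) + n_res
        return {k: v for k, v in counts.items() if v > 0}

    def params(self) -> ParameterSet:
        return get_preset(self.condition)


@dataclass
class SimulationState:
    """Mutable lattice + per-agent state between ticks.

    Agent attribute arrays are indexed by agent id; slots past ``n_agents``
    are unused headroom, and dead agents keep their slot until the arrays
    are compacted.  ``grid`` holds the occupying agent id or -1.
    """

    lattice: LatticeConfig
    grid: np.ndarray          # (height, width) int64, agent id or -1
    kind: np.ndarray          # int64 kind codes
    row: np.ndarray
    col: np.ndarray
    divisions_remaining: np.ndarray
    kills_remaining: np.ndarray
    engagement_remaining: np.ndarray
    alive: np.ndarray         # uint8
    n_agents: int
    tick: int
    base_seed: int
    tick_hours: float = DEFAULT_TICK_HOURS
    counts: np.ndarray = None  # live agents per kind code, shape (6,)

    def __post_init__(self):
        if self.counts is None:
            self.counts = self._recount()

    def _recount(self) -> np.ndarray:
        live = self.alive[: self.n_agents] == 1
        return np.bincount(self.kind[: self.n_agents][live], minlength=6
                           ).astype(np.int64)

    def count(self, kind_name: str) -> int:
        return int(self.counts[KIND_CODES[kind_name]])

    @property
    def time_hours(self) -> float:
        return self.tick * self.tick_hours

    def snapshot(self) -> np.ndarray:
        """Integer-coded occupancy grid (0 empty, kind codes otherwise)."""
        snap = np.zeros(self.grid.shape, dtype=np.int64)
        occ = self.grid >= 0
        snap[occ] = self.kind[self.grid[occ]]
        return snap

    def live_positions(self, kind_name: str) -> np.ndarray:
        """(n, 2) array of (row, col) of live agents of one kind."""
        code = KIND_CODES[kind_name]
        sel = (self.alive[: self.n_agents] == 1) & \
              (self.kind[: self.n_agents] == code)
        return np.column_stack([self.row[: self.n_agents][sel],
                                self.col[: self.n_agents][sel]])

    # -- internal maintenance ------------------------------------------
    def _ensure_headroom(self):
        """Births in one tick are bounded by the live-agent count."""
        needed = self.n_agents + int(self.counts.sum())
        if needed > self.kind.shape[0]:
            new_cap = max(needed, 2 * self.kind.shape[0])
            for name in ("kind", "row", "col", "divisions_remaining",
                         "kills_remaining", "engagement_remaining", "alive"):
                arr = getattr(self, name)
                grown = np.zeros(new_cap, dtype=arr.dtype)
                grown[: arr.shape[0]] = arr
                setattr(self, name, grown)

    def _maybe_compact(self):
        """Drop dead slots when they dominate, to keep kernel scans short."""
        n_live = int(self.counts.sum())
        if self.n_agents > 4096 and self.n_agents > 3 * max(n_live, 1):
            keep = np.flatnonzero(self.alive[: self.n_agents] == 1)
            for name in ("kind", "row", "col", "divisions_remaining",
                         "kills_remaining", "engagement_remaining", "alive"):
                arr = getattr(self, name)
                compacted = np.zeros(arr.shape[0], dtype=arr.dtype)
                compacted[: keep.shape[0]] = arr[keep]
                setattr(self, name, compacted)
            self.n_agents = int(keep.shape[0])
            self.grid.fill(-1)
            self.grid[self.row[: self.n_agents],
                      self.col[: self.n_agents]] = \
                np.arange(self.n_agents, dtype=np.int64)


_KILL_LOG_COLUMNS = ("killer_kind", "killer_row", "killer_col",
                     "victim_kind", "victim_row", "victim_col")


@dataclass
class TickEvents:
    """Bookkeeping of one tick: births/deaths/kills per kind code (len 6)
    plus the per-kill event log (killer and victim kinds and positions)."""

    births: np.ndarray
    deaths: np.ndarray
    kills: np.ndarray
    _kl: tuple = ()      # raw kill-log arrays from the kernel
    _n_ev: int = 0

    @property
    def kill_log(self) -> pd.DataFrame:
        data = {name: (arr[: self._n_ev] if self._n_ev else
                       np.zeros(0, np.int64))
                for name, arr in zip(_KILL_LOG_COLUMNS,
                                     self._kl or [None] * 6)}
        return pd.DataFrame(data)


@dataclass
class Trajectory:
    """Per-tick population counts (and optional snapshots) of one run.

    ``counts`` has shape (ticks + 1, 6) indexed by kind code; row 0 is the
    initial state.  ``births``/``deaths``/``kills`` have shape (ticks, 6) and
    satisfy, per kind, counts[t+1] - counts[t] = births - deaths - kills.
    """

    config: ScenarioConfig
    seed: int
    counts: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    kills: np.ndarray
    snapshots: list  # list of (tick, int grid)
    tick_hours: float = DEFAULT_TICK_HOURS
    kill_logs: list = field(default_factory=list)

    @property
    def times_hours(self) -> np.ndarray:
        return np.arange(self.counts.shape[0]) * self.tick_hours

    def count_series(self, kind_name: str) -> np.ndarray:
        if kind_name == "tumor_total":
            return self.counts[:, 1] + self.counts[:, 2]
        return self.counts[:, KIND_CODES[kind_name]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times_hours, "tick":
                           np.arange(self.counts.shape[0])})
        for name, code in KIND_CODES.items():
            df[name] = self.counts[:, code]
        df["tumor_total"] = df["tumor"] + df["tumor_resistant"]
        return df


# ----------------------------------------------------------------------
def moore_neighbors(position: tuple, lattice: LatticeConfig) -> list:
    """All in-bounds positions at Chebyshev distance 1 (no wraparound)."""
    r, c = position
    if not (0 <= r < lattice.height and 0 <= c < lattice.width):
        raise ValueError(f"position {position} outside "
                         f"{lattice.height}x{lattice.width} grid")
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < lattice.height and 0 <= cc < lattice.width:
                out.append((rr, cc))
    return out


def _tick_seed(base_seed: int, tick: int) -> int:
    """Deterministic per-tick 32-bit seed for the kernel RNG.

    SplitMix64 finalizer over (base_seed, tick): decorrelated per-tick
    streams at negligible construction cost.
    """
    M = (1 << 64) - 1
    z = ((base_seed & M) * 0x9E3779B97F4A7C15 + (tick + 1)
         * 0xBF58476D1CE4E5B9) & M
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & M
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & M
    return int((z ^ (z >> 31)) & 0xFFFFFFFF)


def initialize_state(config: ScenarioConfig, seed: int,
                     params: ParameterSet | None = None) -> SimulationState:
    """Scatter the configured agents uniformly at random, without collision.

    Tumor agents start with their full division capacity, macrophages with
    their full kill capacity and no engagement.  Identical seeds yield
    identical placements.
    """
    if params is None:
        params = config.params()
    lat = config.lattice
    counts = config.effective_counts()
    total = sum(counts.values())
    if total > lat.n_cells:
        raise ValueError(f"{total} agents exceed lattice capacity "
                         f"{lat.n_cells}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    flat = rng.choice(lat.n_cells, size=total, replace=False)
    rows = (flat // lat.width).astype(np.int64)
    cols = (flat % lat.width).astype(np.int64)

    cap = max(2 * total + 64, total + lat.n_cells // 4)
    kind = np.zeros(cap, np.int64)
    row = np.zeros(cap, np.int64)
    col = np.zeros(cap, np.int64)
    divs = np.zeros(cap, np.int64)
    kills = np.zeros(cap, np.int64)
    engage = np.zeros(cap, np.int64)
    alive = np.zeros(cap, np.uint8)

    init_divs = {
        "tumor": params.TUpmax,
        "tumor_resistant": params.TUpmaxres,
        "fibroblast": params.Fpmax,
    }
    init_kills = {"M1": params.M1kmax, "M2": params.M2kmax}

    i = 0
    for kname in ("tumor", "tumor_resistant", "fibroblast", "M1", "M2"):
        for _ in range(counts.get(kname, 0)):
            kind[i] = KIND_CODES[kname]
            row[i], col[i] = rows[i], cols[i]
            divs[i] = init_divs.get(kname, 0)
            kills[i] = init_kills.get(kname, 0)
            alive[i] = 1
            i += 1

    grid = np.full((lat.height, lat.width), -1, dtype=np.int64)
    grid[row[:total], col[:total]] = np.arange(total, dtype=np.int64)
    return SimulationState(
        lattice=lat, grid=grid, kind=kind, row=row, col=col,
        divisions_remaining=divs, kills_remaining=kills,
        engagement_remaining=engage, alive=alive,
        n_agents=total, tick=0, base_seed=int(seed),
    )


def effective_tumor_pprol(params: ParameterSet, state: SimulationState | None,
                          is_resistant: bool = False) -> float:
    """Division probability a tumor agent experiences in the given state.

    M2 macrophages secrete growth-promoting factors modeled as a global
    additive bonus: any live M2 anywhere raises the sensitive-cell division
    probability by ``M2TUadd`` (clamped to 1).  Resistant cells use their
    own rate and receive no bonus.
    """
    if is_resistant:
        return params.TUpprolres
    p = params.TUpprol
    if state is not None and state.counts[K.KIND_M2] > 0:
        p += params.M2TUadd
    return min(1.0, p)


def advance_one_tick(state: SimulationState,
                     params: ParameterSet) -> TickEvents:
    """Resolve one 4-hour tick in place and return its event bookkeeping."""
    state._ensure_headroom()
    births = np.zeros(6, np.int64)
    deaths = np.zeros(6, np.int64)
    killed = np.zeros(6, np.int64)
    max_ev = max(int(state.counts[K.KIND_M1] + state.counts[K.KIND_M2]), 1)
    kl = [np.zeros(max_ev, np.int64) for _ in range(6)]
    n_agents, n_ev = K._advance_tick(
        state.grid, state.kind, state.row, state.col,
        state.divisions_remaining, state.kills_remaining,
        state.engagement_remaining, state.alive,
        state.n_agents, params.pack(), state.counts,
        _tick_seed(state.base_seed, state.tick),
        births, deaths, killed, *kl)
    state.n_agents = int(n_agents)
    state.tick += 1
    state._maybe_compact()
    return TickEvents(births=births, deaths=deaths, kills=killed,
                      _kl=tuple(kl), _n_ev=int(n_ev))


def run_simulation(config: ScenarioConfig,
                   params: ParameterSet | None = None,
                   seed: int = 0,
                   snapshot_ticks: tuple = (),
                   record_kill_log: bool = False) -> Trajectory:
    """Run a scenario for its configured number of ticks.

    Returns per-tick counts for every agent kind, the birth/death/kill
    ledger, and integer-coded grid snapshots at the requested ticks.
    Reproducible: identical (config, params, seed) give identical output.
    """
    if params is None:
        params = config.params()
    state = initialize_state(config, seed, params)
    ticks = config.ticks
    counts = np.zeros((ticks + 1, 6), np.int64)
    births = np.zeros((ticks, 6), np.int64)
    deaths = np.zeros((ticks, 6), np.int64)
    kills = np.zeros((ticks, 6), np.int64)
    snapshots = []
    kill_logs = []
    snapshot_ticks = set(snapshot_ticks)
    counts[0] = state.counts
    if 0 in snapshot_ticks:
        snapshots.append((0, state.snapshot()))
    P = params.pack()
    max_ev = max(int(state.counts[K.KIND_M1] + state.counts[K.KIND_M2]), 1)
    kl = [np.zeros(max_ev, np.int64) for _ in range(6)]
    for t in range(ticks):
        state._ensure_headroom()
        n_agents, n_ev = K._advance_tick(
            state.grid, state.kind, state.row, state.col,
            state.divisions_remaining, state.kills_remaining,
            state.engagement_remaining, state.alive,
            state.n_agents, P, state.counts,
            _tick_seed(state.base_seed, state.tick),
            births[t], deaths[t], kills[t], *kl)
        state.n_agents = int(n_agents)
        state.tick += 1
        state._maybe_compact()
        counts[t + 1] = state.counts
        if record_kill_log and n_ev:
            kill_logs.append((t + 1, pd.DataFrame(
                {name: arr[:n_ev].copy()
                 for name, arr in zip(_KILL_LOG_COLUMNS, kl)})))
        if t + 1 in snapshot_ticks:
            snapshots.append((t + 1, state.snapshot()))
    return Trajectory(config=config, seed=int(seed), counts=counts,
                      births=births, deaths=deaths, kills=kills,
                      snapshots=snapshots, tick_hours=state.tick_hours,
                      kill_logs=kill_logs)


# ----------------------------------------------------------------------
# Single-agent resolution, exposed for fine-grained inspection.  These call
# the same kernels the tick loop uses, after seeding the kernel RNG.

def _agent_at(state: SimulationState, position: tuple) -> int:
    i = int(state.grid[position])
    if i < 0:
        raise ValueError(f"no agent at {position}")
    return i


def resolve_tumor_action(state: SimulationState, position: tuple,
                         params: ParameterSet, seed: int = 0) -> TickEvents:
    """Resolve one tumor agent's turn (death/divide/migrate/idle)."""
    i = _agent_at(state, position)
    if state.kind[i] not in (K.KIND_TUMOR, K.KIND_RESISTANT):
        raise ValueError("agent is not a tumor cell")
    state._ensure_headroom()
    K._seed_rng(int(seed) % 2**32)
    births = np.zeros(6, np.int64)
    deaths = np.zeros(6, np.int64)
    fib_ids = K._collect_ids(state.kind, state.alive, state.n_agents,
                             K.KIND_FIBROBLAST, K.KIND_FIBROBLAST)
    nr8 = np.empty(8, np.int64)
    nc8 = np.empty(8, np.int64)
    state.n_agents = int(K._resolve_tumor(
        i, state.grid, state.kind, state.row, state.col,
        state.divisions_remaining, state.kills_remaining,
        state.engagement_remaining, state.alive, state.n_agents,
        params.pack(), state.counts, fib_ids, births, deaths, nr8, nc8))
    return TickEvents(births, deaths, np.zeros(6, np.int64))


def resolve_fibroblast_action(state: SimulationState, position: tuple,
                              params: ParameterSet,
                              seed: int = 0) -> TickEvents:
    """Resolve one fibroblast's turn (death/divide/migrate/idle)."""
    i = _agent_at(state, position)
    if state.kind[i] != K.KIND_FIBROBLAST:
        raise ValueError("agent is not a fibroblast")
    state._ensure_headroom()
    K._seed_rng(int(seed) % 2**32)
    births = np.zeros(6, np.int64)
    deaths = np.zeros(6, np.int64)
    tu_ids = K._collect_ids(state.kind, state.alive, state.n_agents,
                            K.KIND_TUMOR, K.KIND_RESISTANT)
    nr8 = np.empty(8, np.int64)
    nc8 = np.empty(8, np.int64)
    state.n_agents = int(K._resolve_fibroblast(
        i, state.grid, state.kind, state.row, state.col,
        state.divisions_remaining, state.kills_remaining,
        state.engagement_remaining, state.alive, state.n_agents,
        params.pack(), state.counts, tu_ids, births, deaths, nr8, nc8))
    return TickEvents(births, deaths, np.zeros(6, np.int64))


def resolve_macrophage_action(state: SimulationState, position: tuple,
                              params: ParameterSet,
                              seed: int = 0) -> TickEvents:
    """Resolve one macrophage's turn (engage/die/kill/migrate/idle)."""
    i = _agent_at(state, position)
    if state.kind[i] not in (K.KIND_M1, K.KIND_M2):
        raise ValueError("agent is not a macrophage")
    K._seed_rng(int(seed) % 2**32)
    deaths = np.zeros(6, np.int64)
    killed = np.zeros(6, np.int64)
    kl = [np.zeros(4, np.int64) for _ in range(6)]
    tu_ids = K._collect_ids(state.kind, state.alive, state.n_agents,
                            K.KIND_TUMOR, K.KIND_RESISTANT)
    P = params.pack()
    if state.kind[i] == K.KIND_M1:
        pkill, pmig, rwalk = params.M1pkill, params.M1pmig, params.M1rwalk
        speed, engdur = params.M1speed, params.M1engagementDuration
    else:
        pkill, pmig, rwalk = params.M2pkill, params.M2pmig, params.M2rwalk
        speed, engdur = params.M2speed, params.M2engagementDuration
    nr8 = np.empty(8, np.int64)
    nc8 = np.empty(8, np.int64)
    n_ev = K._resolve_macrophage(
        i, state.grid, state.kind, state.row, state.col,
        state.divisions_remaining, state.kills_remaining,
        state.engagement_remaining, state.alive, P, state.counts, tu_ids,
        deaths, killed, *kl, 0, pkill, pmig, rwalk,
        np.int64(speed), np.int64(engdur), nr8, nc8)
    return TickEvents(np.zeros(6, np.int64), deaths, killed,
                      _kl=tuple(kl), _n_ev=int(n_ev))
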