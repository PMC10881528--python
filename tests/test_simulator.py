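import numpy as np
import pytest

import pcabm
from pcabm import (KIND_CODES, LatticeConfig, ParameterSet, ScenarioConfig,
                   SimulationState, advance_one_tick, effective_tumor_pprol,
                   get_preset, initialize_state, moore_neighbors,
                   resolve_fibroblast_action, resolve_macrophage_action,
                   resolve_tumor_action, run_simulation)

from conftest import make_config


def make_state(lattice, agents, base_seed=0):
    """Hand-built state: agents = [(kind_name, row, col, divs, kills), ...]."""
    n = len(agents)
    cap = 2 * n + 64
    kind = np.zeros(cap, np.int64)
    row = np.zeros(cap, np.int64)
    col = np.zeros(cap, np.int64)
    divs = np.zeros(cap, np.int64)
    kills = np.zeros(cap, np.int64)
    engage = np.zeros(cap, np.int64)
    alive = np.zeros(cap, np.uint8)
    grid = np.full((lattice.height, lattice.width), -1, np.int64)
    for i, (kname, r, c, d, k) in enumerate(agents):
        kind[i] = KIND_CODES[kname]
        row[i], col[i] = r, c
        divs[i], kills[i] = d, k
        alive[i] = 1
        grid[r, c] = i
    return SimulationState(lattice=lattice, grid=grid, kind=kind, row=row,
                           col=col, divisions_remaining=divs,
                           kills_remaining=kills,
                           engagement_remaining=engage, alive=alive,
                           n_agents=n, tick=0, base_seed=base_seed)


# ----------------------------------------------------------------------
# Neighborhood geometry
def test_moore_neighborhood_center_edge_corner(small_lattice):
    assert len(moore_neighbors((10, 10), small_lattice)) == 8
    assert len(moore_neighbors((0, 10), small_lattice)) == 5
    corner = moore_neighbors((0, 0), small_lattice)
    assert sorted(corner) == [(0, 1), (1, 0), (1, 1)]
    assert all(max(abs(r - 10), abs(c - 10)) == 1
               for r, c in moore_neighbors((10, 10), small_lattice))


def test_moore_neighborhood_rejects_out_of_bounds(small_lattice):
    with pytest.raises(ValueError):
        moore_neighbors((25, 0), small_lattice)


# ----------------------------------------------------------------------
# Initialization
def test_initialization_counts_and_exclusivity(small_lattice):
    cfg = make_config({"tumor": 50, "fibroblast": 20, "M1": 5, "M2": 5},
                      lattice=small_lattice)
    st = initialize_state(cfg, seed=3)
    assert st.count("tumor") == 50 and st.count("fibroblast") == 20
    assert st.count("M1") == 5 and st.count("M2") == 5
    occ = st.grid[st.grid >= 0]
    assert len(occ) == 80 and len(np.unique(occ)) == 80  # one agent per cell
    # grid and coordinate arrays agree
    for i in occ:
        assert st.grid[st.row[i], st.col[i]] == i


def test_initialization_is_seed_deterministic(small_lattice):
    cfg = make_config({"tumor": 30, "M2": 4}, lattice=small_lattice)
    a = initialize_state(cfg, seed=7)
    b = initialize_state(cfg, seed=7)
    c = initialize_state(cfg, seed=8)
    assert np.array_equal(a.grid, b.grid)
    assert not np.array_equal(a.grid, c.grid)


def test_initial_capacities_match_parameters(small_lattice, preset_d):
    cfg = make_config({"tumor": 10, "M1": 3}, lattice=small_lattice,
                      condition="DMSO", resistant_fraction=0.2)
    st = initialize_state(cfg, seed=0)
    k = st.kind[: st.n_agents]
    assert np.all(st.divisions_remaining[: st.n_agents][k == 1]
                  == preset_d.TUpmax)
    assert np.all(st.divisions_remaining[: st.n_agents][k == 2]
                  == preset_d.TUpmaxres)
    assert np.all(st.kills_remaining[: st.n_agents][k == 4]
                  == preset_d.M1kmax)


def test_resistant_fraction_splits_tumor_seeding(small_lattice):
    cfg = make_config({"tumor": 100}, lattice=small_lattice,
                      resistant_fraction=1.0 / 101.0 * 1.01)  # = 1/100
    counts = cfg.effective_counts()
    assert counts["tumor"] + counts["tumor_resistant"] == 100
    assert counts["tumor_resistant"] == 1


def test_overfull_lattice_rejected():
    with pytest.raises(ValueError, match="capacity"):
        make_config({"tumor": 700}, lattice=LatticeConfig(25, 25))


# ----------------------------------------------------------------------
# Effective proliferation probability (M2 growth bonus)
def test_m2_bonus_raises_sensitive_tumor_division(small_lattice, preset_r):
    no_m2 = initialize_state(make_config({"tumor": 5},
                                         lattice=small_lattice), seed=0)
    with_m2 = initialize_state(make_config({"tumor": 5, "M2": 1},
                                           lattice=small_lattice), seed=0)
    assert effective_tumor_pprol(preset_r, no_m2) == pytest.approx(0.1144)
    assert effective_tumor_pprol(preset_r, with_m2) == pytest.approx(0.2139)
    # resistant cells use their own rate and receive no bonus
    d = get_preset("DMSO")
    assert effective_tumor_pprol(d, with_m2, is_resistant=True) \
        == pytest.approx(0.0596)
    assert effective_tumor_pprol(d, no_m2) == pytest.approx(0.0389)


# ----------------------------------------------------------------------
# Forced single-agent branches
def test_certain_death_removes_tumor_cell(small_lattice):
    st = make_state(small_lattice, [("tumor", 12, 12, 4, 0)])
    p = ParameterSet(TUpdeath=1.0)
    ev = resolve_tumor_action(st, (12, 12), p, seed=1)
    assert st.count("tumor") == 0 and st.grid[12, 12] == -1
    assert ev.deaths[KIND_CODES["tumor"]] == 1


def test_certain_division_places_daughter_in_moore_neighborhood(
        small_lattice):
    st = make_state(small_lattice, [("tumor", 12, 12, 4, 0)])
    p = ParameterSet(TUpprol=1.0, TUpdeath=0.0, TUpres=0.0, M2TUadd=0.0)
    ev = resolve_tumor_action(st, (12, 12), p, seed=1)
    assert st.count("tumor") == 2
    assert ev.births[KIND_CODES["tumor"]] == 1
    pos = st.live_positions("tumor")
    d = np.max(np.abs(pos[0] - pos[1]))
    assert d == 1  # Chebyshev-adjacent
    # inheritance: parent AND daughter carry the decremented capacity
    assert list(st.divisions_remaining[:2]) == [3, 3]


def test_division_with_certain_resistance_switch(small_lattice):
    st = make_state(small_lattice, [("tumor", 12, 12, 4, 0)])
    p = ParameterSet(TUpprol=1.0, TUpdeath=0.0, TUpres=1.0, TUpprolres=0.06,
                     TUpmaxres=50, M2TUadd=0.0)
    resolve_tumor_action(st, (12, 12), p, seed=1)
    assert st.count("tumor") == 1 and st.count("tumor_resistant") == 1
    i_res = int(np.flatnonzero(st.kind[:2] == 2)[0])
    assert st.divisions_remaining[i_res] == 50  # fresh resistant capacity
    assert st.divisions_remaining[1 - i_res] == 3


def test_exhausted_capacity_falls_through_to_migration(small_lattice):
    st = make_state(small_lattice, [("tumor", 12, 12, 0, 0)])
    p = ParameterSet(TUpprol=1.0, TUpdeath=0.0, TUpmig=1.0, M2TUadd=0.0)
    resolve_tumor_action(st, (12, 12), p, seed=1)
    assert st.count("tumor") == 1  # no division possible
    r, c = st.live_positions("tumor")[0]
    assert max(abs(r - 12), abs(c - 12)) == 1  # migrated one step


def test_blocked_neighborhood_degrades_to_idle(small_lattice):
    agents = [("tumor", 12, 12, 4, 0)]
    for r, c in moore_neighbors((12, 12), small_lattice):
        agents.append(("fibroblast", r, c, 0, 0))
    st = make_state(small_lattice, agents)
    p = ParameterSet(TUpprol=1.0, TUpdeath=0.0, TUpmig=1.0, M2TUadd=0.0)
    resolve_tumor_action(st, (12, 12), p, seed=1)
    assert st.count("tumor") == 1
    assert st.grid[12, 12] == 0  # did not move
    assert st.divisions_remaining[0] == 4  # blocked attempt costs no capacity


def test_fibroblast_division_and_death(small_lattice):
    st = make_state(small_lattice, [("fibroblast", 5, 5, 10, 0)])
    grow = ParameterSet(Fpprol=1.0, Fpdeath=0.0)
    resolve_fibroblast_action(st, (5, 5), grow, seed=1)
    assert st.count("fibroblast") == 2
    st2 = make_state(small_lattice, [("fibroblast", 5, 5, 10, 0)])
    die = ParameterSet(Fpdeath=1.0)
    resolve_fibroblast_action(st2, (5, 5), die, seed=1)
    assert st2.count("fibroblast") == 0


def test_macrophage_kill_consumes_capacity_and_sets_engagement(
        small_lattice):
    st = make_state(small_lattice, [("M1", 10, 10, 0, 11),
                                    ("tumor", 10, 11, 4, 0)])
    p = ParameterSet(M1pkill=1.0)
    ev = resolve_macrophage_action(st, (10, 10), p, seed=1)
    assert st.count("tumor") == 0
    assert ev.kills[KIND_CODES["tumor"]] == 1
    assert st.kills_remaining[0] == 10
    assert st.engagement_remaining[0] == p.M1engagementDuration == 60
    log = ev.kill_log
    assert len(log) == 1
    assert log.loc[0, "killer_kind"] == KIND_CODES["M1"]
    assert log.loc[0, "victim_kind"] == KIND_CODES["tumor"]


def test_engagement_blocks_actions_and_wears_off_at_speed(small_lattice):
    st = make_state(small_lattice, [("M1", 10, 10, 0, 11),
                                    ("tumor", 10, 11, 4, 0),
                                    ("tumor", 10, 9, 4, 0)])
    p = ParameterSet(M1pkill=1.0)
    resolve_macrophage_action(st, (10, 10), p, seed=1)  # kill -> engaged 60
    assert st.count("tumor") == 1
    resolve_macrophage_action(st, (10, 10), p, seed=2)
    assert st.engagement_remaining[0] == 20  # 60 - speed(40)
    assert st.count("tumor") == 1            # blocked, no second kill
    resolve_macrophage_action(st, (10, 10), p, seed=3)
    assert st.engagement_remaining[0] == 0
    assert st.count("tumor") == 1
    resolve_macrophage_action(st, (10, 10), p, seed=4)
    assert st.count("tumor") == 0            # free again: kills


def test_exhausted_macrophage_cannot_kill(small_lattice):
    st = make_state(small_lattice, [("M1", 10, 10, 0, 0),
                                    ("tumor", 10, 11, 4, 0)])
    p = ParameterSet(M1pkill=1.0)
    resolve_macrophage_action(st, (10, 10), p, seed=1)
    assert st.count("tumor") == 1


def test_directed_macrophage_migration_stops_adjacent_to_tumor(
        small_lattice):
    st = make_state(small_lattice, [("M1", 0, 0, 0, 11),
                                    ("tumor", 20, 20, 4, 0)])
    p = ParameterSet(M1pkill=0.0, M1pmig=1.0, M1rwalk=0.0)  # fully directed
    resolve_macrophage_action(st, (0, 0), p, seed=1)
    r, c = st.live_positions("M1")[0]
    assert max(abs(r - 20), abs(c - 20)) == 1  # reached contact and stopped


# ----------------------------------------------------------------------
# Whole-tick behavior
def test_unconstrained_growth_doubles_until_capacity(small_lattice):
    st = make_state(small_lattice, [("tumor", 12, 12, 4, 0)])
    p = ParameterSet(TUpprol=1.0, TUpdeath=0.0, TUpmig=0.0, TUpres=0.0,
                     M2TUadd=0.0)
    for t, expected in [(1, 2), (2, 4), (3, 8)]:
        advance_one_tick(st, p)
        # newborns idle on their birth tick, so growth is exactly x2
        assert st.count("tumor") == expected


def test_conservation_ledger_balances_every_tick(preset_r):
    cfg = make_config({"tumor": 60, "fibroblast": 15, "M1": 15},
                      ticks=20, condition="R1881")
    traj = run_simulation(cfg, seed=5)
    delta = np.diff(traj.counts, axis=0)
    assert np.array_equal(delta, traj.births - traj.deaths - traj.kills)


def test_identical_seeds_reproduce_identical_trajectories():
    cfg = make_config({"tumor": 50, "fibroblast": 12, "M2": 6}, ticks=15)
    a = run_simulation(cfg, seed=11)
    b = run_simulation(cfg, seed=11)
    c = run_simulation(cfg, seed=12)
    assert np.array_equal(a.counts, b.counts)
    assert not np.array_equal(a.counts, c.counts)


def test_snapshot_codes_match_live_counts(small_lattice):
    cfg = make_config({"tumor": 40, "fibroblast": 10, "M1": 4, "M2": 3},
                      lattice=small_lattice, ticks=5)
    traj = run_simulation(cfg, seed=2, snapshot_ticks=(5,))
    tick, snap = traj.snapshots[0]
    assert tick == 5
    for name, code in KIND_CODES.items():
        assert int((snap == code).sum()) == traj.count_series(name)[-1]


def test_trajectory_frame_and_total_series():
    cfg = make_config({"tumor": 50}, ticks=8, condition="DMSO",
                      resistant_fraction=0.1)
    traj = run_simulation(cfg, seed=4)
    df = traj.to_frame()
    assert list(df["time_h"])[:3] == [0.0, 4.0, 8.0]
    assert np.array_equal(df["tumor_total"],
                          df["tumor"] + df["tumor_resistant"])
    assert np.array_equal(traj.count_series("tumor_total"),
                          df["tumor_total"].to_numpy())
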