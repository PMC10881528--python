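import numpy as np
import pytest

from pcabm import (CATALOG, LatticeConfig, build_scenario,
                   clustering_permutation_pvalue, fold_change,
                   fold_change_report, get_preset,
                   nearest_neighbor_clustering, relative_growth,
                   run_simulation, scenario_names)
from pcabm.scenarios import scenario_from_dict, scenario_to_dict

from conftest import make_config


def test_catalog_covers_both_conditions():
    names = scenario_names()
    assert len(names) == len(set(names)) == len(CATALOG)
    assert "LNCaP_DMSO" in names and "LNCaP_R1881" in names
    assert "CRPC_F_41_DMSO" in names
    assert sum(n.endswith("_DMSO") for n in names) == \
        sum(n.endswith("_R1881") for n in names)


def test_build_scenario_applies_culture_ratios():
    cfg = build_scenario("LNCaP_F_41_DMSO", base_count=1000)
    assert cfg.counts == {"tumor": 1000, "fibroblast": 250}
    assert cfg.condition == "DMSO" and cfg.ticks == 42
    cfg = build_scenario("M1_TU_F_111_R1881", base_count=400)
    assert cfg.counts == {"tumor": 400, "M1": 400, "fibroblast": 400}
    cfg = build_scenario("CRPC_DMSO", base_count=1010)
    eff = cfg.effective_counts()
    assert eff["tumor_resistant"] == 10 and eff["tumor"] == 1000


def test_resistant_monoculture_scenario_is_fully_resistant():
    cfg = build_scenario("LNCaP_abl_DMSO", base_count=50)
    eff = cfg.effective_counts()
    assert eff == {"tumor_resistant": 50}


def test_unknown_scenario_name_lists_catalog():
    with pytest.raises(KeyError, match="LNCaP_DMSO"):
        build_scenario("HeLa_DMSO")


def test_scenario_dict_round_trip():
    cfg = build_scenario("LNCaP_F_M2_411_R1881", base_count=200,
                         lattice=LatticeConfig(50, 50))
    assert scenario_from_dict(scenario_to_dict(cfg)) == cfg


def test_relative_growth_normalizes_at_24_hours():
    cfg = make_config({"tumor": 80}, ticks=10)
    traj = run_simulation(cfg, seed=1)
    curve = relative_growth(traj, kind="tumor_total", t0_hours=24.0)
    i24 = int(np.argmin(np.abs(curve.times - 24.0)))
    assert curve.times[i24] == 24.0 and curve.values[i24] == 1.0
    counts = traj.count_series("tumor_total")
    np.testing.assert_allclose(curve.values, counts / counts[6])


def test_relative_growth_rejects_off_grid_normalization_time():
    traj = run_simulation(make_config({"tumor": 20}, ticks=10), seed=1)
    with pytest.raises(ValueError, match="recorded tick"):
        relative_growth(traj, t0_hours=200.0)  # beyond the 40-h run


def test_relative_growth_rejects_zero_baseline():
    traj = run_simulation(make_config({"fibroblast": 10}, ticks=10), seed=1)
    with pytest.raises(ValueError, match="zero"):
        relative_growth(traj, kind="tumor_total", t0_hours=24.0)


def test_fold_change_worked_example():
    assert fold_change(6.0, 2.0) == 3.0
    r = get_preset("R1881")
    d = get_preset("DMSO")
    ratio, nearest = fold_change_report(r.TUpprol, d.TUpprol)
    assert ratio == pytest.approx(0.1144 / 0.0389)
    assert nearest == 3
    with pytest.raises(ValueError, match="denominator"):
        fold_change(1.0, 0.0)


# ----------------------------------------------------------------------
# Clustering index oracles
def _snapshot_with(points, shape=(60, 60), code=2):
    snap = np.zeros(shape, np.int64)
    for r, c in points:
        snap[r, c] = code
    return snap


def test_clustering_index_near_one_for_uniform_placement():
    rng = np.random.default_rng(42)
    flat = rng.choice(60 * 60, size=120, replace=False)
    snap = _snapshot_with(np.column_stack([flat // 60, flat % 60]))
    idx = nearest_neighbor_clustering(snap, "tumor_resistant", seed=0)
    assert 0.9 < idx < 1.1


def test_clustering_index_detects_compact_focus():
    pts = [(r, c) for r in range(10, 21) for c in range(10, 21)]
    snap = _snapshot_with(pts)
    idx = nearest_neighbor_clustering(snap, "tumor_resistant", seed=0)
    assert idx < 0.5
    p = clustering_permutation_pvalue(snap, "tumor_resistant", n_perm=199,
                                      seed=0)
    assert p <= 0.01


def test_clustering_index_undefined_below_two_agents():
    snap = _snapshot_with([(5, 5)])
    with pytest.raises(ValueError, match="need >= 2"):
        nearest_neighbor_clustering(snap, "tumor_resistant")


def test_clustering_index_is_seed_deterministic():
    pts = [(r, c) for r in range(5, 9) for c in range(5, 9)]
    snap = _snapshot_with(pts)
    a = nearest_neighbor_clustering(snap, "tumor_resistant", seed=3)
    b = nearest_neighbor_clustering(snap, "tumor_resistant", seed=3)
    assert a == b
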