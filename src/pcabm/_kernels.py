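"""Numba kernels for the lattice tick loop.

All state lives in flat numpy arrays indexed by agent id; ``grid`` holds the
id of the occupying agent or -1.  Kind codes (shared with snapshot exports):
1 tumor, 2 resistant tumor, 3 fibroblast, 4 M1 macrophage, 5 M2 macrophage.

The packed parameter vector ``P`` follows ``ParameterSet._PACK_ORDER``:

    0 TUpprol   1 TUpmig    2 TUpdeath  3 TUrwalk   4 TUpmax
    5 TUpres    6 TUpprolres 7 TUpmigres 8 TUpmaxres
    9 M1pkill  10 M1pmig   11 M1rwalk  12 M1kmax   13 M1speed
   14 M1engagementDuration
   15 M2pkill  16 M2pmig   17 M2rwalk  18 M2kmax   19 M2speed
   20 M2engagementDuration 21 M2TUadd
   22 Fpprol   23 Fpmig    24 Fpdeath  25 Frwalk   26 Fpmax
   27 Mpdeath

Each agent resolves at most one action per tick, drawn sequentially:
spontaneous death, then proliferation (dividers) or killing (macrophages),
then migration, else idle.  Migration is a single-cell move for dividers and
up to ``speed`` sub-steps for macrophages.  Directed moves aim at the free
Moore neighbor closest (Euclidean) to the nearest live target agent.
"""

import numpy as np
from numba import njit

# Parameter indices (kept in sync with ParameterSet._PACK_ORDER).
I_TUPPROL, I_TUPMIG, I_TUPDEATH, I_TURWALK, I_TUPMAX = 0, 1, 2, 3, 4
I_TUPRES, I_TUPPROLRES, I_TUPMIGRES, I_TUPMAXRES = 5, 6, 7, 8
I_M1PKILL, I_M1PMIG, I_M1RWALK, I_M1KMAX, I_M1SPEED, I_M1ENG = 9, 10, 11, 12, 13, 14
I_M2PKILL, I_M2PMIG, I_M2RWALK, I_M2KMAX, I_M2SPEED, I_M2ENG = 15, 16, 17, 18, 19, 20
I_M2TUADD = 21
I_FPPROL, I_FPMIG, I_FPDEATH, I_FRWALK, I_FPMAX = 22, 23, 24, 25, 26
I_MPDEATH = 27

KIND_TUMOR = 1
KIND_RESISTANT = 2
KIND_FIBROBLAST = 3
KIND_M1 = 4
KIND_M2 = 5


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _collect_ids(kind, alive, n_agents, k1, k2):
    cnt = 0
    for i in range(n_agents):
        if alive[i] == 1 and (kind[i] == k1 or kind[i] == k2):
            cnt += 1
    out = np.empty(cnt, np.int64)
    j = 0
    for i in range(n_agents):
        if alive[i] == 1 and (kind[i] == k1 or kind[i] == k2):
            out[j] = i
            j += 1
    return out


@njit(cache=True)
def _free_neighbors(grid, r, c, nr, nc):
    """Fill nr/nc with in-bounds empty Moore neighbors; return how many."""
    H, W = grid.shape
    n = 0
    for dr in range(-1, 2):
        for dc in range(-1, 2):
            if dr == 0 and dc == 0:
                continue
            rr = r + dr
            cc = c + dc
            if 0 <= rr < H and 0 <= cc < W and grid[rr, cc] < 0:
                nr[n] = rr
                nc[n] = cc
                n += 1
    return n


@njit(cache=True)
def _nearest_target(row, col, alive, target_ids, r0, c0):
    """Id of nearest (squared-Euclidean) live agent among target_ids, or -1."""
    best = -1
    bd = np.int64(1) << 62
    for k in range(target_ids.shape[0]):
        i = target_ids[k]
        if alive[i] == 1:
            d = (row[i] - r0) ** 2 + (col[i] - c0) ** 2
            if d < bd:
                bd = d
                best = i
    return best


@njit(cache=True)
def _pick_directed(nfree, nr, nc, tr, tc):
    """Index of the free neighbor nearest to (tr, tc); ties broken uniformly."""
    bd = np.int64(1) << 62
    for k in range(nfree):
        d = (nr[k] - tr) ** 2 + (nc[k] - tc) ** 2
        if d < bd:
            bd = d
    cnt = 0
    for k in range(nfree):
        if (nr[k] - tr) ** 2 + (nc[k] - tc) ** 2 == bd:
            cnt += 1
    pick = np.random.randint(cnt)
    for k in range(nfree):
        if (nr[k] - tr) ** 2 + (nc[k] - tc) ** 2 == bd:
            if pick == 0:
                return k
            pick -= 1
    return 0  # unreachable


@njit(cache=True)
def _move(i, grid, row, col, rr, cc):
    grid[row[i], col[i]] = -1
    grid[rr, cc] = i
    row[i] = rr
    col[i] = cc


@njit(cache=True)
def _migrate_one_step(i, grid, row, col, alive, rwalk, target_ids, nr8, nc8):
    """One single-cell move; returns True if the agent moved."""
    nfree = _free_neighbors(grid, row[i], col[i], nr8, nc8)
    if nfree == 0:
        return False
    if np.random.random() < rwalk:
        k = np.random.randint(nfree)
    else:
        t = _nearest_target(row, col, alive, target_ids, row[i], col[i])
        if t < 0:
            k = np.random.randint(nfree)
        else:
            k = _pick_directed(nfree, nr8, nc8, row[t], col[t])
    _move(i, grid, row, col, nr8[k], nc8[k])
    return True


@njit(cache=True)
def _tumor_adjacent(grid, kind, r, c):
    H, W = grid.shape
    for dr in range(-1, 2):
        for dc in range(-1, 2):
            if dr == 0 and dc == 0:
                continue
            rr = r + dr
            cc = c + dc
            if 0 <= rr < H and 0 <= cc < W:
                a = grid[rr, cc]
                if a >= 0 and (kind[a] == KIND_TUMOR or kind[a] == KIND_RESISTANT):
                    return True
    return False


@njit(cache=True)
def _die(i, grid, kind, alive, row, col, counts):
    alive[i] = 0
    grid[row[i], col[i]] = -1
    counts[kind[i]] -= 1


@njit(cache=True)
def _resolve_tumor(i, grid, kind, row, col, divs, kills, engage, alive,
                   n_agents, P, counts, fib_ids, births, deaths, nr8, nc8):
    """One tumor agent's turn: death -> proliferation -> migration -> idle."""
    resistant = kind[i] == KIND_RESISTANT
    if np.random.random() < P[I_TUPDEATH]:
        _die(i, grid, kind, alive, row, col, counts)
        deaths[kind[i]] += 1
        return n_agents
    if resistant:
        pprol = P[I_TUPPROLRES]
    else:
        pprol = P[I_TUPPROL]
        if counts[KIND_M2] > 0:
            pprol = min(1.0, pprol + P[I_M2TUADD])
    # Capacity-exhausted cells never attempt division and fall through to
    # migration; an attempted division blocked by a full neighborhood
    # consumes the turn.
    if divs[i] > 0 and np.random.random() < pprol:
        nfree = _free_neighbors(grid, row[i], col[i], nr8, nc8)
        if nfree > 0:
            k = np.random.randint(nfree)
            d = n_agents
            divs[i] -= 1
            if not resistant and np.random.random() < P[I_TUPRES]:
                kind[d] = KIND_RESISTANT
                divs[d] = np.int64(P[I_TUPMAXRES])
            else:
                kind[d] = kind[i]
                divs[d] = divs[i]
            row[d] = nr8[k]
            col[d] = nc8[k]
            kills[d] = 0
            engage[d] = 0
            alive[d] = 1
            grid[nr8[k], nc8[k]] = d
            counts[kind[d]] += 1
            births[kind[d]] += 1
            return n_agents + 1
        return n_agents  # blocked division consumes the turn
    pmig = P[I_TUPMIGRES] if resistant else P[I_TUPMIG]
    if np.random.random() < pmig:
        _migrate_one_step(i, grid, row, col, alive, P[I_TURWALK], fib_ids,
                          nr8, nc8)
    return n_agents


@njit(cache=True)
def _resolve_fibroblast(i, grid, kind, row, col, divs, kills, engage, alive,
                        n_agents, P, counts, tu_ids, births, deaths,
                        nr8, nc8):
    """One fibroblast's turn; directed migration targets the nearest tumor."""
    if np.random.random() < P[I_FPDEATH]:
        _die(i, grid, kind, alive, row, col, counts)
        deaths[KIND_FIBROBLAST] += 1
        return n_agents
    if divs[i] > 0 and np.random.random() < P[I_FPPROL]:
        nfree = _free_neighbors(grid, row[i], col[i], nr8, nc8)
        if nfree > 0:
            k = np.random.randint(nfree)
            d = n_agents
            divs[i] -= 1
            kind[d] = KIND_FIBROBLAST
            divs[d] = divs[i]
            row[d] = nr8[k]
            col[d] = nc8[k]
            kills[d] = 0
            engage[d] = 0
            alive[d] = 1
            grid[nr8[k], nc8[k]] = d
            counts[KIND_FIBROBLAST] += 1
            births[KIND_FIBROBLAST] += 1
            return n_agents + 1
        return n_agents
    if np.random.random() < P[I_FPMIG]:
        _migrate_one_step(i, grid, row, col, alive, P[I_FRWALK], tu_ids,
                          nr8, nc8)
    return n_agents


@njit(cache=True)
def _resolve_macrophage(i, grid, kind, row, col, divs, kills, engage, alive,
                        P, counts, tu_ids, deaths, killed,
                        kl_kkind, kl_kr, kl_kc, kl_vkind, kl_vr, kl_vc, n_ev,
                        pkill, pmig, rwalk, speed, engdur, nr8, nc8):
    """One macrophage's turn: engaged -> death -> kill -> migrate -> idle.

    A post-kill engagement is worked off at ``speed`` sub-steps per tick and
    blocks all other actions.  Directed migration stops early once a tumor
    cell is Moore-adjacent.
    """
    if engage[i] > 0:
        engage[i] = max(np.int64(0), engage[i] - speed)
        return n_ev
    if np.random.random() < P[I_MPDEATH]:
        _die(i, grid, kind, alive, row, col, counts)
        deaths[kind[i]] += 1
        return n_ev
    if kills[i] > 0:
        # collect Moore-adjacent live tumor cells
        nadj = 0
        H, W = grid.shape
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                rr = row[i] + dr
                cc = col[i] + dc
                if 0 <= rr < H and 0 <= cc < W:
                    a = grid[rr, cc]
                    if a >= 0 and (kind[a] == KIND_TUMOR
                                   or kind[a] == KIND_RESISTANT):
                        nr8[nadj] = rr
                        nc8[nadj] = cc
                        nadj += 1
        if nadj > 0 and np.random.random() < pkill:
            k = np.random.randint(nadj)
            v = grid[nr8[k], nc8[k]]
            killed[kind[v]] += 1
            kl_kkind[n_ev] = kind[i]
            kl_kr[n_ev] = row[i]
            kl_kc[n_ev] = col[i]
            kl_vkind[n_ev] = kind[v]
            kl_vr[n_ev] = row[v]
            kl_vc[n_ev] = col[v]
            _die(v, grid, kind, alive, row, col, counts)
            kills[i] -= 1
            engage[i] = engdur
            return n_ev + 1
    if np.random.random() < pmig:
        for _ in range(speed):
            if _tumor_adjacent(grid, kind, row[i], col[i]):
                break
            if not _migrate_one_step(i, grid, row, col, alive, rwalk, tu_ids,
                                     nr8, nc8):
                break
    return n_ev


@njit(cache=True)
def _advance_tick(grid, kind, row, col, divs, kills, engage, alive,
                  n_agents, P, counts, seed,
                  births, deaths, killed,
                  kl_kkind, kl_kr, kl_kc, kl_vkind, kl_vr, kl_vc):
    """Resolve one 4-hour tick: tumor, fibroblast, M1, M2 phases in order.

    Agents of each phase are collected (and shuffled) at phase start, so
    agents born during the tick idle until the next one.  Returns the new
    agent-array high-water mark and the number of kill events logged.
    """
    _seed_rng(seed)
    nr8 = np.empty(8, np.int64)
    nc8 = np.empty(8, np.int64)
    n_ev = 0

    # --- tumor phase (sensitive and resistant share one shuffled queue) ---
    tu_ids = _collect_ids(kind, alive, n_agents, KIND_TUMOR, KIND_RESISTANT)
    fib_ids = _collect_ids(kind, alive, n_agents, KIND_FIBROBLAST,
                           KIND_FIBROBLAST)
    order = np.random.permutation(tu_ids.shape[0])
    for k in range(order.shape[0]):
        i = tu_ids[order[k]]
        if alive[i] == 1:
            n_agents = _resolve_tumor(i, grid, kind, row, col, divs, kills,
                                      engage, alive, n_agents, P, counts,
                                      fib_ids, births, deaths, nr8, nc8)

    # --- fibroblast phase (targets include daughters born this tick) ---
    tu_ids = _collect_ids(kind, alive, n_agents, KIND_TUMOR, KIND_RESISTANT)
    f_ids = _collect_ids(kind, alive, n_agents, KIND_FIBROBLAST,
                         KIND_FIBROBLAST)
    order = np.random.permutation(f_ids.shape[0])
    for k in range(order.shape[0]):
        i = f_ids[order[k]]
        if alive[i] == 1:
            n_agents = _resolve_fibroblast(i, grid, kind, row, col, divs,
                                           kills, engage, alive, n_agents, P,
                                           counts, tu_ids, births, deaths,
                                           nr8, nc8)

    # --- M1 then M2 macrophage phases ---
    m1_ids = _collect_ids(kind, alive, n_agents, KIND_M1, KIND_M1)
    order = np.random.permutation(m1_ids.shape[0])
    for k in range(order.shape[0]):
        i = m1_ids[order[k]]
        if alive[i] == 1:
            n_ev = _resolve_macrophage(
                i, grid, kind, row, col, divs, kills, engage, alive, P,
                counts, tu_ids, deaths, killed,
                kl_kkind, kl_kr, kl_kc, kl_vkind, kl_vr, kl_vc, n_ev,
                P[I_M1PKILL], P[I_M1PMIG], P[I_M1RWALK],
                np.int64(P[I_M1SPEED]), np.int64(P[I_M1ENG]), nr8, nc8)

    m2_ids = _collect_ids(kind, alive, n_agents, KIND_M2, KIND_M2)
    order = np.random.permutation(m2_ids.shape[0])
    for k in range(order.shape[0]):
        i = m2_ids[order[k]]
        if alive[i] == 1:
            n_ev = _resolve_macrophage(
                i, grid, kind, row, col, divs, kills, engage, alive, P,
                counts, tu_ids, deaths, killed,
                kl_kkind, kl_kr, kl_kc, kl_vkind, kl_vr, kl_vc, n_ev,
                P[I_M2PKILL], P[I_M2PMIG], P[I_M2RWALK],
                np.int64(P[I_M2SPEED]), np.int64(P[I_M2ENG]), nr8, nc8)

    return n_agents, n_ev
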