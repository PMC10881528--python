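# Model and methods

## 1. The lattice model

### State

The domain is a bounded rectangular grid (default 125×125; no wraparound,
modeling a culture well). Each grid cell has the footprint of one tumor cell
(142.89 µm²) and holds at most one agent. Agent kinds and their integer
codes (shared by state arrays, snapshot exports, and the rendering palette):

| code | kind | palette |
|------|------|---------|
| 0 | empty | white |
| 1 | androgen-sensitive tumor cell | red |
| 2 | castration-resistant tumor cell | dark red |
| 3 | fibroblast | green |
| 4 | M1 macrophage | dark blue |
| 5 | M2 macrophage | light blue |

Per-agent state: position, kind, remaining division capacity (tumor,
fibroblast), remaining kill capacity and engagement counter (macrophages).

### Tick loop

Time advances in 4-hour ticks (42 ticks = 168 h, the 7-day assay). Within a
tick the phases run in the fixed order **tumor → fibroblast → M1 → M2**.
At the start of each phase the live agents of that phase are collected and
shuffled, then resolved sequentially; agents born during a tick idle until
the next tick. Each agent resolves **at most one action**, drawn in
sequence:

1. **Spontaneous death** with probability `pdeath` (tumor, fibroblast;
   macrophage death `Mpdeath` defaults to 0): the agent is removed.
2. **Division** (tumor, fibroblast), attempted only while the agent's
   division capacity is positive, with probability `pprol`: the daughter is
   placed on a uniformly random free Moore neighbor. Parent *and* daughter
   both carry the parent's decremented capacity. A division attempt blocked
   by a full neighborhood consumes the turn (degrades to idle) without
   spending capacity. A sensitive tumor daughter switches to the resistant
   phenotype with probability `TUpres`, starting with the fresh resistant
   capacity `TUpmaxres`.
   **Kill** (macrophages), attempted while kill capacity is positive, with
   probability `pkill` if a live tumor cell is Moore-adjacent: a uniformly
   random adjacent tumor cell is removed, the kill capacity decrements, and
   the engagement counter is set to `engagementDuration`.
3. **Migration** with probability `pmig`: a move to a free Moore neighbor.
   With probability `rwalk` the step is uniformly random among free
   neighbors; otherwise it is directed — the free neighbor closest
   (squared Euclidean, ties uniform) to the nearest live target agent
   (tumor cells target fibroblasts; fibroblasts and macrophages target
   tumor cells). Tumor cells and fibroblasts make one single-cell step;
   macrophages make up to `speed` sub-steps per tick and stop early once a
   tumor cell is Moore-adjacent.
4. Otherwise **idle**.

A macrophage whose engagement counter is positive does nothing that tick
except work the counter down by `speed`.

M2 influence is global: while at least one M2 macrophage is alive, the
sensitive tumor division probability is `TUpprol + M2TUadd` (clamped to 1).
Resistant cells use `TUpprolres`/`TUpmigres` and receive no bonus.

### Parameters and presets

All probabilities are per 4-hour tick. Two calibrated presets ship, one per
hormone condition of the co-culture experiments ("DCC" = hormone-stripped
medium; DMSO = vehicle, R1881 = synthetic androgen):

| parameter | DCC DMSO | DCC R1881 | meaning |
|---|---|---|---|
| TUpprol | 0.0389 | 0.1144 | tumor division probability |
| TUpmig | 0.1 | 0.1167 | tumor migration probability |
| TUpdeath | 0.00248 | 0.00248 | tumor death probability |
| TUrwalk | 0.5 | 0.5 | random share of tumor steps |
| TUpmax | 4 | 4 | tumor division capacity |
| TUpres | 0.002 | 0 | sensitive→resistant switch per division |
| TUpprolres | 0.0596 | 0 | resistant division probability |
| TUpmigres | 0.1167 | 0 | resistant migration probability |
| TUpmaxres | 50 | 0 | resistant division capacity |
| M1pkill | 0.005 | 0.1116 | M1 kill probability |
| M2pkill | 0.0348 | 0.0223 | M2 kill probability |
| M2TUadd | 0 | 0.0995 | M2 bonus to sensitive division |
| M1/M2 pmig | 0.2667 | 0.2667 | macrophage migration probability |
| M1/M2 rwalk | 0.8 | 0.8 | random share of macrophage steps |
| M1/M2 kmax | 11 | 11 | kill capacity |
| M1/M2 speed | 40 | 40 | migration sub-steps per tick |
| engagementDuration | 60 | 60 | post-kill refractory sub-steps |
| Fpprol | 0.0838 | 0.0838 | fibroblast division probability |
| Fpmig | 0.4 | 0.4 | fibroblast migration probability |
| Fpdeath | 0.0018 | 0.0018 | fibroblast death probability |
| Frwalk | 0.5 | 0.5 | random share of fibroblast steps |
| Fpmax | unlimited | unlimited | fibroblast division capacity |

The resistant phenotype is switched off in the R1881 preset: castration
resistance has no selective meaning under androgen stimulation.

A second table, `NO_FIBROBLAST_REFITS`, carries the refitted values for
tumor + macrophage cultures *without* fibroblasts (used to separate
tumor-intrinsic proliferation changes from macrophage killing): M1pkill
rises to 0.2034 under R1881 (0.005 under DMSO), and in the M2 context
TUpprol is 0.0384/0.1128 with M2pkill 0.0219/0.0441 (DMSO/R1881).

### Scenario catalog

Named scenarios mirror the calibration cultures: tumor and resistant-tumor
monocultures, fibroblast monoculture, tumor:fibroblast 4:1 and 1:1,
tumor:fibroblast:macrophage 4:1:1 (M1 or M2), tumor:macrophage 4:1 without
fibroblasts, macrophage-dose variants (M:TU:F 1:4:1 and 1:1:1), and CRPC
scenarios seeded with one resistant per 100 sensitive cells. Every scenario
exists in both conditions; the default seeding is 1000 tumor cells (≈6.4%
of the default grid), with the other populations scaled by the culture
ratio.

## 2. Growth curves and reporting

Trajectories record per-tick counts per kind plus a per-tick ledger of
births, deaths, and kills that closes exactly:
`counts[t+1] − counts[t] = births − deaths − kills`.

`relative_growth` normalizes a count series to its value at 24 h, the
convention of the live-cell-imaging curves the model is calibrated to.

Spatial clustering of a population in a snapshot is quantified by a
Clark–Evans-style index: the observed mean nearest-neighbor distance
divided by its expectation under uniform random *collision-free* placement
of the same number of agents on the same grid. The null expectation is
estimated by Monte Carlo (default 199 seeded placements) rather than the
continuous-plane closed form 0.5/√density, because the discrete lattice
and collision exclusion bias the closed form; Monte Carlo makes "uniform
placement → index ≈ 1" exact by construction. Values below 1 indicate
clustering; a one-sided permutation test (`clustering_permutation_pvalue`)
is also provided.

## 3. Calibration

### Cost

A candidate parameter vector is scored by simulating the scenario
`n_sim_rep` times (distinct derived seeds), averaging the relative growth
curves, and taking the mean squared error against the data curve (data
times matched to the nearest tick; a mismatch beyond half a tick is an
error).

### Particle swarm

Global-best PSO with constriction-style defaults (inertia 0.729, cognitive
= social = 1.49445), velocities clamped to half each dimension's range,
reflecting bounds. All particles of an iteration share one evaluation seed
(common random numbers), which reduces noise-induced rank flips between
candidates. Fits are restarted many times (default 50); the reported
estimate is the per-parameter median across restarts (for multi-replicate
data: the median across biological replicates of per-replicate medians)
with the interquartile range as spread. Restarts whose final cost exceeds
100× the best restart's cost are flagged non-converged and excluded from
the median: on a multimodal cost surface, restarts trapped in a spurious
basin report costs orders of magnitude above converged ones (evaluation
noise only perturbs costs by factors of a few), and a plain median over
all restarts can land in the wrong basin. This matters in practice for
the hormone-deprived tumor monoculture stage, where curves normalized at
24 h admit a spurious high-proliferation fit — an early burst that
exhausts the division capacity before the normalization point mimics slow
growth — whose cost sits ~600× above the true basin. Integer capacities are searched on
a continuous scale and rounded at evaluation time. Default bounds:
probabilities [0, 0.5], M2TUadd [0, 0.3], capacities [1, 20], resistant
capacity [1, 60].

### Staged protocol

Parameters are fitted in stages against the matching culture's growth
curves, freezing each stage's result before the next: (1) tumor
monoculture under R1881 fits TUpprol and TUpmax, the capacity assumed
hormone-independent and copied to DMSO; (2) tumor monoculture under DMSO
fits TUpprol; (3) fibroblast monoculture fits Fpprol and Fpdeath, copied
across conditions; (4–5) the 4:1:1 M1 co-culture fits M1pkill (and, under
R1881, M1kmax, reused for M2); (6–7) the 4:1:1 M2 co-culture fits M2pkill
and M2TUadd; (8–10) optional no-fibroblast refits; (11) the resistant
monoculture fits TUpprolres and TUpmaxres.

## 4. Synthetic data

`generate_logistic_dataset` produces datasets with the structure of the
imaging experiments — two conditions × 3 biological × 6 technical
replicates × 43 time points (0–168 h every 4 h) — from a logistic mean
curve n(t) = K/(1 + ((K−n0)/n0)e^(−rt)) with multiplicative log-normal
noise (default sd 0.05, a placeholder, not an estimate of the real data's
noise), renormalized per series at 24 h. `generate_simulated_dataset` uses
the simulator itself, one run per technical replicate, for
parameter-recovery experiments with known ground truth.

## 5. Numerical choices

- **Kernels.** The tick loop runs in numba-compiled kernels over flat
  int64 arrays; the Python dataclass layer wraps them. Dead agents keep
  their array slot until slots are compacted (when dead slots outnumber
  live agents 3:1 beyond 4096 entries).
- **Randomness.** One kernel RNG stream per tick, seeded deterministically
  from (base seed, tick) via a SplitMix64 finalizer. Runs are bit-exactly
  reproducible given (scenario, parameters, seed); replicate, restart, and
  evaluation seeds derive from `numpy.random.SeedSequence`.
- **Sparse-limit oracle.** In a sparse monoculture the expected tumor
  count follows an exact dynamic program over the division-capacity
  ladder; while no lineage can have exhausted its capacity it collapses to
  N₀((1−d)(1+p))ᵗ ≈ N₀(1+p−d)ᵗ. Under the R1881 preset the capacity
  (TUpmax = 4, inherited decremented by both daughters) starts to bind
  near tick 10, pulling the mean ~2% below the capacity-free closed form;
  the DP tracks the simulator within Monte Carlo error throughout. The
  acceptance suite applies the capacity-free closed form as its stated
  oracle and therefore flags this point; see `tests/test_branching.py` for
  the exact oracle.
- **Reduced recovery problems.** The parameter-recovery acceptance checks
  run on a 40×40 grid seeded with 100 tumor cells (the same density as the
  full default) with one biological replicate, n_sim_rep = 2, and a
  reduced PSO (10 restarts, swarm 15, 40 iterations) so the whole suite
  stays within a desk-scale compute budget. These sizes are a package
  choice; full-scale fits use the same code paths. At this size the M1
  kill probability is only weakly identified: with 25 M1 macrophages the
  total kill signal is tens of cells against the stochastic growth of
  ~100-cell runs, and the recovery cost surface is flat to within its own
  evaluation noise across roughly [0.08, 0.2] (measured costs 0.03±0.03
  at 0.08, 0.05±0.02 at the generating 0.1116, 0.01±0.01 at 0.15,
  0.04±0.03 at 0.2). The fitted value tracks the noise minimum of the
  particular dataset (~0.15 for the shipped seed, ~34% high) rather than
  failing to optimize; tighter recovery requires more replicates or a
  larger grid. The other recovery targets (TUpprol both conditions,
  M2TUadd) are sharply identified and recover within 5%.

## 6. Limitations

- Macrophages neither die (by default), proliferate, nor repolarize; the
  M2 growth bonus is global rather than distance-weighted.
- No nutrient, oxygen, or drug pharmacokinetics; hormone conditions enter
  only through the parameter presets.
- The synthetic-data generator emulates the *shape* of imaging-derived
  growth curves, not imaging artifacts or absolute fluorescence units.
- Calibration targets relative growth curves only; spatial statistics are
  reported but not fitted.
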