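# Methods

## Model

The process is a discrete-time susceptible–infected (SI) contagion on a
simple undirected graph `G(V, E)`, extended with per-node habituation.

**Seeding (step 0).** `k = max(1, round(SP·|V|))` nodes are infected
(round half up; `SP` is the seed fraction).  `ranking=degree` takes the `k`
highest-degree nodes, ties broken by ascending node identifier;
`ranking=random` samples uniformly without replacement.

**Contagion step.** Every node infected before the step is a spreader — SI
spreaders never deactivate, and nodes infected during step `s` first act in
step `s+1`.  Spreaders are visited in shuffled order; each spreader's
currently susceptible neighbours are shuffled too.  Each contact consumes one
uniform draw `x` and infects the target `v` iff `x ≤ PP·R(v)`.  A node
infected earlier within the step is excluded from later spreaders' neighbour
lists (no draw is consumed for it).

**Habituation.** Each failed contact immediately updates the target:
`R(v) = y0 − (S/α)(1 − e^(−α·c/τ))` with `c` its total failed-contact count,
so later contacts *within the same step* already face the reduced level.
Infection freezes a node's responsiveness at its value at infection time
(it only matters for reporting thereafter).  The counter unit is contacts,
not steps: a node attacked three times in one step habituates three times.

**Tie rule.** A draw exactly equal to the threshold infects (`≤`).  The
`strict_inequality` switch provides the `<` variant for sensitivity checks;
it changes outcomes only on measure-zero events for random draws, but
matters for scripted-draw traces.

**Recovery.** During a step in which a previously-contacted, still
susceptible node receives no contact, `recovery_enabled` applies one tick of
`y(t) = y0 − (y0 − y1)e^(−α(t−1)/τ)`, where `y1` is the level when the
decline stopped and `t` counts quiet periods (the `t=1` boundary leaves the
level unchanged).  It is off by default: with persistent SI spreaders a
susceptible node with an infected neighbour is contacted every step, so the
rebound never fires in practice.

**Stopping.** A run ends when coverage (infected fraction, seeds included)
reaches the coverage target — 80% by default, chosen because the final
approach to full coverage is extremely slow — or at the `max_steps` cap
(default 1000), recorded as `stop_reason`.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `pp` | base propagation probability per contact | 0.1 | study levels 0.05, 0.1 |
| `seed_fraction` | fraction of nodes seeded at step 0 | 0.01 | study levels 0.01, 0.05 |
| `ranking` | seed strategy | `random` | or `degree` |
| `S` | stimulus per contact | 1.0 | one attempt = one stimulus unit |
| `alpha` | decay-floor / recovery rate constant | 1.05 | study levels 1.05, 1.2; floor `y0−S/α` must be ≥ 0 (validated, not clamped) |
| `tau` | habituation time constant (contacts) | 5 | study levels 5–25; small = fast habituation |
| `y0` | baseline responsiveness | 1.0 | |
| `coverage_target` | stop threshold | 0.80 | |
| `max_steps` | step cap | 1000 | guards non-terminating low-`pp` runs |

Useful identities: the floor is `1 − 1/α` for `S = y0 = 1` (0.0476 at
α=1.05, 0.1667 at α=1.2), which is why larger α spreads faster; larger τ
means a higher `R` at any failure count, so coverage is non-decreasing in τ.

## Randomness and reproducibility

Each run derives two independent RNG streams from its single `rng_seed`: one
for the per-step shuffles of spreader/neighbour order, one for the
per-contact uniforms (a third stream drives random seeding).  Exactly one
uniform is consumed per contact whether or not habituation is enabled.  Two
contracts follow, both under test: (1) a habituation-free run and a run with
numerically negligible habituation (τ = 10¹²) produce identical
trajectories under the same seed; (2) replaying the uniforms recorded from a
live run through the scripted-draw harness reproduces it exactly, because the
shuffle stream is regenerated from the same seed.  Grid runs get per-run
seeds from a SHA-256 hash of (base seed, combination index, replicate), so
results are independent of execution order and partial grids resume cleanly.

Within-step contact order is randomized (spreaders and neighbour lists
shuffled) because updates are immediate and order therefore matters; fixed
id-order would introduce a systematic bias.

## Factorial experiment and aggregation

The default grid crosses ranking (2) × network (4) × PP (2) × SP (2) ×
habituation (2) × α (2) × τ (5) = 640 combinations, 10 replicates each
(6400 runs); α and τ are enumerated even in habituation-off cells so the
combination count and pairing mirror the full design.  Each run records
coverage after 5/10/15 steps (a run that stopped earlier holds its final
value) and the first step reaching 40% and 80% coverage.

Aggregation pools all runs per grouping value (rather than averaging
replicate means first).  When grouping by α or τ the habituation-free
baseline is the pool of *all* habituation-off runs, since those factors are
inert there — which is why the baseline column repeats across α/τ rows.
Arms are compared with the two-sided Mann–Whitney rank-sum test (runs are
unpaired samples; where a signed-rank test is wanted the same samples can be
paired by seed outside the harness).  Effect sizes are the relative coverage
decrease `100·(noHab − hab)/noHab` and relative duration increase
`100·(hab − noHab)/noHab`.  Runs that hit the step cap contribute missing
durations; they are excluded from duration means and the excluded count is
reported per cell.  Degenerate rank tests (all pooled values identical)
return p = 1 with a warning.

## Synthetic data

`make_stand_in_networks` builds four Barabási–Albert graphs with
(n, m) = (899, 8), (1224, 14), (1858, 7), (1899, 7), matching the node
counts and mean degrees (≈ 15.9, 27.7, 13.9, 13.9) of four published social
networks of comparable scale; preferential attachment gives the heavy-tailed
degree distribution typical of such networks.  They do **not** match those
networks' clustering, eigenvector centrality or modularity, and BA graphs
have no degree-1 tail (minimum degree = m), so results on the stand-ins
demonstrate the direction and rough magnitude of the habituation effect, not
network-specific cell values.  The bundled seven-node toy graph fixes four
documented ties plus four filler edges and is an approximation for
demonstrating the kinetics, not a reconstruction of any particular trace.

## Problem sizes used in the checks

The stochastic acceptance checks use 100 matched-seed replicates on the
n=899 stand-in (`pp=0.05`, `SP=0.01`, random seeding, α=1.05): full runs
(step cap 400) for the habituation-free arm and τ=5, and 10-step runs for
τ ∈ {10, 15, 20, 25}, which are compared at step 10 only.  The cap of 400 is
comfortable: with minimum degree 8 the per-node infection hazard even at the
responsiveness floor is ≳ 2% per step, and observed τ=5 durations cluster
near 60–120 steps.  These sizes give standard errors of the step-10 coverage
means of well under one percentage point, separating adjacent τ levels.

## Numerical notes and limitations

- The decay law saturates at the floor in double precision once
  `e^(−αc/τ)` underflows relative to 1 (c·α/τ ≳ 37); monotonicity is then
  non-strict.  No clamping is applied anywhere: parameter sets with a
  negative floor are rejected at construction.
- Durations are in steps and integer-valued; coverage is in multiples of
  1/|V|.
- Graphs are coerced to simple undirected; self-loops are dropped on read
  with a warning, directed GraphML is rejected.
- Edge "weights" are not static attributes: each contact draws a fresh
  uniform, modelling per-occasion receptivity.
- The harness reports unpaired rank-sum p-values only; it does not model
  competing cascades, SIR/SIRS recovery from *infection*, or parameter
  fitting of the kinetics to empirical response data.
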