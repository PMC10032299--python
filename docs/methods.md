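# Methods

## Model overview

`termite_transport` is an individual-based (agent-based) model of food
transport by subterranean termites through a fixed foraging tunnel. The
tunnel is a one-dimensional lattice of `L+1 = 1001` sites `x = 0..1000`
tracing the sinusoid `y = 20 sin(pi x / 500)`; the transverse profile is
metadata (plotting only), because every behavioral rule depends only on the
arc position. Site `x = 0` opens into the nest, `x = 1000` into a food site
that never runs out. One hundred agents are placed uniformly at random on
the interior sites at `t = 0`, empty-handed, facing the nest or the food
with equal probability, and the world is advanced for `T = 5000` discrete
steps. Pheromone signalling, tunnel excavation and variable tunnel width are
outside the model's scope.

Four integer control levels, each in 1..11, set the environment and the
agents' response to it:

| level | meaning | mapping | default channel |
|---|---|---|---|
| `k1` | tunnel-curvature effect | per-step stop probability `(k1-1) * 0.05` inside the zones `235 <= x <= 265` and `735 <= x <= 765` | slows traffic stochastically |
| `k2` | inspection time at irregularities | pause `tau ~ Poisson(lambda)`, `lambda = (k2-1) * 5` steps | holds agents in place |
| `k3` | irregularity distribution | sites eligible where `sin(2 pi f x / L) > 0`, `f = (k3-1) * 2` | patchiness of the layout |
| `k4` | irregularity density | `(k4-1) * 30` distinct sites sampled uniformly without replacement from the eligible set | number of pause sites |

`k3 = 1` gives `f = 0`; the gating sine vanishes identically, which we read
as "no spatial structure": every interior site is eligible, so the layout is
uniform. Endpoints are never eligible, so pickup and deposit are never
delayed by a pause at a terminus. Strict positivity of the gating sine is
evaluated in exact integer arithmetic (`(f*x) mod L` in `(0, L/2)`), which
removes float noise at the lattice zeros of the sine. If `(k4-1)*30` exceeds
the eligible-set size (possible only on scaled-down test tunnels), the
layout truncates to the whole eligible set and logs a warning.

## One time step

Phases run in a fixed order; all randomness flows through one
`numpy.random.Generator`, so a run is bit-reproducible from its seed.

1. **Timers.** PAUSED/JAMMED timers decrement; an agent whose timer reaches
   zero becomes MOVING but walks again only on the *next* step, so a freeze
   of length `d` suppresses exactly `d` moves.
2. **Movement.** Each MOVING agent inside a curvature zone draws one uniform
   number and stops for the step if it falls below `(k1-1)*0.05`; every other
   MOVING agent advances one site in its facing direction (speed is one site
   per step). An empty agent arriving at the food site picks up a fresh
   particle (loss count `n = 0`) and turns around; a carrier arriving at the
   nest deposits `max(0, 1 - 0.09 n)` food value and turns around;
   wrong-configuration arrivals (carrier at food, empty at nest) simply
   reverse. An agent arriving on an irregularity site draws
   `tau ~ Poisson(lambda)` and enters PAUSED for `tau` steps when `tau > 0`
   (`lambda = 0` short-circuits to no pause). Re-entering a site re-triggers
   the draw; agents keep no memory of visited irregularities.
3. **Transfers (bucket brigade).** When a carrier *meets* an empty agent, a
   hand-off occurs with probability 0.2: the particle moves to the recipient
   with loss count `n+1` and both parties reverse direction. Meetings between
   two carriers never transfer; a carrier meeting several empties picks one
   recipient uniformly at random; an agent takes part in at most one transfer
   per step; JAMMED agents do not transfer (PAUSED agents do).
4. **Jams.** At any site holding four or more non-jammed agents, disjoint
   groups of exactly four with direction sum zero (two facing each way) form
   greedily; each grouped agent freezes for 100 steps and each group logs one
   event `(t, site, 4)`. Agents released from a freeze this very step are
   exempt until they have moved: a released quartet still stands together
   with balanced directions, and without the exemption it would re-jam in
   place indefinitely instead of dispersing on its next move.

### Meeting semantics

The transfer rule hinges on what "meeting" means on a unit-speed lattice,
and the choice changes the transfer rate several-fold. Three readings are
implemented (`BehaviorParams.meeting_rule`):

* `"encounter"` (**default**) — one attempt per *new contact*: the pair
  arrives on a shared site, or the two agents swap adjacent sites during the
  move (they pass each other on the connecting edge — opposite-direction
  walkers whose gap has odd parity never co-locate at integer times, yet
  certainly meet). A pair that stays in contact does not re-attempt every
  step.
* `"site_encounter"` — as above but counting only new same-site contacts;
  odd-parity passes are invisible.
* `"colocated"` — every co-located carrier/empty pair attempts once per step
  for as long as they stand together.

The default follows the observation that termites meeting in opposite
directions antennate while *passing*; it also yields a per-trip hand-off
count (~15-20 over a full nest-bound journey through steady traffic)
consistent with the low delivered food values the efficiency statistic
implies. The `"colocated"` rule lets same-direction pairs fall into
lockstep and exchange the particle indefinitely, grinding its value to zero
while both agents oscillate — we consider that a lattice artifact.

## Transport efficiency

With `food(t)` the food value deposited into the nest at step `t`,

    E(tau) = s * sum_{t<=tau} food(t) / (tau * N0),

with scale `s = 10,000` and `N0 = 100` agents. The sum is thus the
cumulative delivered value `F(tau)`, so `E` saturates under a constant
delivery rate; the alternative reading that re-sums an already-cumulative
series grows without bound under sustained delivery and is exposed as
`efficiency_series(..., mode="cumulative")` for comparison only. Per-run
scalars reported by sweeps are the mean of `E(tau)` over the late-time
saturation window `tau in [3000, 5000]` (configurable; a final-value
alternative is the `E_final` column).

## Sensitivity analysis

The partial rank correlation coefficient (PRCC) of each control level with
the replicate-averaged `E`: all four input columns and the response are
rank-transformed (ties get average ranks), then each ranked input and the
ranked response are regressed (OLS with intercept) on the other three ranked
inputs and the Pearson correlation of the two residual vectors is reported.
PRCC lies in [-1, 1] and is invariant under strictly monotone transformations
of the response; the residual construction is verified in the test suite
against the precision-matrix identity and against an independent
partial-correlation implementation to 1e-10. Designs are either the full
factorial over chosen levels (the full experiment is 11^4 cells x 10
replicates = 146,410 runs) or a Latin hypercube: `n` strata per dimension,
one draw per stratum, independently permuted across dimensions, mapped onto
[0.5, 11.5] and rounded to integer levels. Responses are replicate-averaged
per design row by default (`per_replicate=True` uses every run). No p-values
are attached; a permutation null band (`prcc_null_band`) is available.

## Seeding

Every run derives its generator as `default_rng([master_seed, *path])` where
`path` is a counter path (cell index, replicate index) recorded in the run's
JSON sidecar, so any single run of a sweep is reproducible in isolation.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the reference conditions at
`T = 5000` with 100 agents: the no-irregularity baseline (10 replicates),
the `k4 = 1..11` jam sweep at `k2 = 6` (10 replicates per level), the
`{1,4,8,11}^4` factorial for the PRCC ordering (3 replicates), and the
11x11 `(k3, k4)` efficiency map at `k2 = 6` (3 replicates). The map and the
factorial use fewer replicates than the full study design purely as the
package's scaled-down reproduction recipe. The `(k3, k4)` map is run at
`k2 = 6` because pauses have zero length at `k2 = 1`, which would leave the
irregularity levels without any channel to affect `E`.

## Known limitations

* **Shape of the baseline E(t).** With `k1 = k2 = 1` and no irregularities,
  the replicate-averaged efficiency rises over the first ~2,000 steps and
  saturates near 0.01 rather than peaking early and decaying. Under the
  stated rules the early delivery wave travels through a population that is
  still mostly empty-handed, so it suffers *more* lossy hand-offs than
  steady-state traffic — the model has no mechanism that makes the early
  delivery rate exceed the late one. The corresponding shape check in the
  acceptance tests is expected to fail and is left failing deliberately.
* **Location of the jam maximum.** Total jam frequency versus irregularity
  density is non-monotone with an interior maximum, but the maximum sits at
  low density (`k4 ~ 2`) for mid pause levels. Jams here are driven by
  pile-ups of paused agents, whose per-site occupancy scales like
  `lambda * S / L` with `S` pause sites; the jam rate peaks near
  `lambda * S ~ L/2`, i.e. at `S ~ 20` sites when `lambda = 25`. A maximum at
  `S = 150` (`k4 = 6`) would require an effective pause length near 3 steps,
  inconsistent with `lambda = (k2-1)*5` at mid `k2`; any pile-up-driven jam
  mechanism is also strongly `lambda`-dependent, whereas the jam response is
  reported as depending only weakly on the pause level.
* **Absolute scale of E.** Delivered value depends steeply on the per-trip
  hand-off count (11 transfers void a particle), hence on the meeting rule;
  absolute `E` values are reliable only to within a small factor, while the
  orderings and signs of the level effects (k4 and k2 dominant and negative,
  k1 weakly negative, k3 negligible) are robust across meeting rules.
* Movement speed, initial interior placement and uniform random initial
  directions are modelling choices where the behavioral rules leave the
  lattice implementation open; they are documented above and fixed across
  all shipped experiments.
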