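# Methods

## Model overview

`wardsim` simulates a nursing-home ward in discrete time. The world state is
a set of variables — continuous agent positions on a walkable-cell grid,
categorical orientation/guidance/task states, counters for the assistive
device — advanced tick by tick under fixed update rules, some of which are
stochastic. One tick is the atomic decision interval; with the default
1 m cells and ~1 cell/tick walking speed, a tick is on the order of a second
of real time, but no result depends on that identification.

Within each tick the update order is fixed:

1. **Orientation transitions.** Each unguided patient: oriented → disoriented
   with probability `dis_level` (a per-decision-point hazard; patients are
   essentially always en route, so this is per tick), disoriented → oriented
   with `reorient_prob` (spontaneous recovery). Nurse-guided patients never
   transition here; release happens when guidance ends.
2. **Smart watch** (smart-watch policies only). Per disoriented, unguided
   patient: detection with per-tick probability `p_detect` (geometric
   detection latency); once detected, a cue every `cue_cooldown` ticks
   starting one cooldown after detection, each succeeding with
   `p_cue_success`; after `n_help` failed cues, one `NURSE_CALLED` per
   episode.
3. **Nurses.** Pending calls are matched oldest-first to the nearest routine
   nurse. Responding nurses pursue the patient's current position at `speed`
   and arrive when within one cell; guiding nurses escort the patient (whose
   position follows the nurse) along the shortest route to the patient's
   destination at `guide_speed`; on arrival the patient reorients. Under
   *Nurse Only*, routine nurses instead discover unguided disoriented
   patients within `discovery_radius`. Under *No Help* this phase is inert.
4. **Patient movement.** Oriented patients advance along their shortest
   route by a step drawn from `max(0, Normal(mean_step, sd_step))`, clamped
   at the destination; on arrival the next destination comes from a cyclic
   per-run shuffled schedule. Disoriented unguided patients take a correlated
   random walk: heading perturbed by a uniform turn in ±`turn_range`
   (default ±90°), steps from the same sampler, non-walkable moves resolved
   by resampling the heading up to 8 times, else staying put.
5. **Recording.** Post-update state of every agent is appended to the state
   table; events carry the tick of the phase that emitted them.

All randomness flows from one `numpy` generator seeded per run, so a
protocol's serialized bytes are a pure function of (configuration, seed).
Batches and sweeps derive run *i*'s seed as `base_seed + i`, and a policy
sweep reuses the same base seed in every arm: paired arms share their random
draws up to the first policy-dependent branch, which reduces the Monte-Carlo
variance of between-policy contrasts.

Runs terminate after a fixed tick horizon rather than on a state condition;
this keeps time-fraction scores comparable across runs and policies.

## Modeling choices that were genuinely open

- **A guided patient stays flagged disoriented until delivered.** Orientation
  flips to oriented only at `GUIDE_END`. This is what makes the two safety
  operationalizations differ, and is the substantive point the package
  exists to demonstrate: `safety_original` counts safely escorted time as
  unsafe, and only comparing its scores across policies exposes that as
  implausible.
- **Spontaneous reorientation** (`reorient_prob`, default 0.005/tick) is a
  small escape hatch so that *No Help* runs are not absorbing — a patient
  lost forever would pin every score at 1. It may be set to 0.
- **Cue timing.** The first cue goes out one cooldown interval after
  detection, then every `cue_cooldown` ticks. Under this timing the call
  under escalation threshold `n` arrives about `n × cue_cooldown` ticks
  after detection, so the threshold has a proportional time cost — the
  quantity the escalation policy is supposed to trade off. (With an
  immediate first cue, thresholds 0 and 1 would differ by a single tick and
  be indistinguishable.)
- **One call per episode.** A call that becomes stale (the patient recovered
  or is already being helped) is dropped with a `CANCELLED` event rather
  than re-issued; this keeps caregiver workload countable.
- **Per-run safety is the mean over patients** (configurable to `max` via
  `builtin_value_models(aggregate="max")`); patient-level scores are kept in
  the result for distributional analysis.
- **Fairness denominator** is pooled nurse duty time (`n_nurses × horizon`),
  the least-assumption reading of "share of caregiver time".

## Default condition and parameter rationale

The shipped demo ward is a generated 25×11-cell corridor-spine layout: six
resident rooms with doorways, a lounge and a dining area at the corridor
ends, two nurse stations on the corridor. The real geometry such a ward
would be based on is not public, so the fixture is synthetic by design.

Defaults (all in `wardsim.demo.DEMO_PARAMS`, overridable in YAML config):
3 patients, 2 nurses, `dis_level` 0.01/tick, `reorient_prob` 0.005,
`mean_step` 1.0 cells, `sd_step` 0.2, `p_detect` 0.1, `p_cue_success` 0.25,
`cue_cooldown` 4 ticks, nurse `speed` 2.0, `guide_speed` 0.6,
`discovery_radius` 2.0 cells, horizon 2000 ticks.

The interesting parameters were chosen from a per-episode renewal
approximation rather than by trial and error. Writing `D = 1/p_detect` for
mean detection latency, `c = cue_cooldown`, `s = p_cue_success`, `T` for mean
call-to-arrival time and `E` for mean escort duration, the mean unguided
disoriented time per episode under threshold `n` is approximately

    U(n) = D + c · Σ_{k=1..n} (1−s)^{k−1} + (1−s)^n · T,

and total disoriented time adds `(1−s)^n · E`. Two qualitative properties
pin down the parameter region:

- *Refined safety increases with the threshold* iff `c > s·T` (each extra
  tolerated failure adds a cooldown of wandering but saves only the chance
  of a nurse trip).
- *Original safety decreases with the threshold* — the demonstrated
  inversion — iff `T + E > c/s` (escorted resolution must be slower than
  cue resolution, because escort time counts as unsafe under the original
  reading).

Measured on the demo ward, `T ≈ 2.5` ticks and `E ≈ 17` ticks at
`guide_speed` 0.6 (escorting a frail person goes at well below free walking
pace), so with `c/s = 16` both inequalities hold with a comfortable margin.
The small `discovery_radius` reflects that, without a telemetry device, a
stationed nurse only notices a wandering resident in their immediate
vicinity; a radius comparable to the corridor length would let two stations
passively surveil most of this small ward and would (unrealistically) make
*Nurse Only* safer than the smart watch.

## What the generator does and does not emulate

The synthetic behavior models stand in for observational data that is not
available: real way-finding of persons with dementia is not a memoryless
Bernoulli process, real detection is not geometric, and the ward geometry is
a cartoon. Passing tests therefore show that the *pipeline* — simulation,
protocol accounting, value scoring, policy comparison — behaves correctly
and that the qualitative safety/fairness structure emerges under plausible
dynamics; they are not evidence about any real facility, resident
population, or device. The shipped value models are worked examples of
operationalization, not validated ethical instruments.

## Numerical and procedural details

- Positions are continuous in cell units (origin top-left, x rightward,
  y downward); the cell of `(x, y)` is `(⌊y⌋, ⌊x⌋)`. Routing is BFS over the
  4-connected walkable grid with BFS trees cached per root cell, so pursuit
  of a moving target is O(path length) per tick. Oriented movement heads for
  the next cell center, which keeps every straight segment inside the convex
  union of two adjacent cells — no wall clipping.
- Step sampling truncates the normal at zero by clipping; at the default
  mean/sd the truncated mass is ≈ 3e-7, so mean and sd are effectively
  unchanged (asserted by test).
- Nurse arrival means "within one cell of the patient"; on a straight
  corridor with the patient `d` cells away this takes `⌈(d−1)/speed⌉` ticks.
- Protocols serialize to JSONL with exact float repr, so
  write∘read is the identity and byte equality is a meaningful determinism
  check. Readers validate the schema line by line (reporting line numbers)
  and then the structural invariants: record count = horizon × agents,
  events sorted by tick, guide start/end alternation, arrivals preceded by a
  call or discovery.
- Scores are clamped to [0, 1]; run-level efficiency with no completed legs
  reports 0 (no evidence of efficient completion) rather than failing,
  since value models must be total on any valid protocol.

## Problem sizes used in the shipped analyses

The reproduction script and the acceptance tests use 200 runs per policy for
the six-policy demo sweep (1200 runs, 2000 ticks each), chosen so that the
smallest asserted contrast (refined safety between adjacent thresholds,
≈ 0.02 score units) sits several standard errors from zero under seed
pairing. The scale-parity check repeats the sweep at 302 runs per policy
(1812 runs total) and asserts the same orderings. Structural invariants are
checked over 1000 randomized short runs spanning all policy variants.

## Known limitations

- Single floor; no doors, locking, or collision; diagonal movement is not
  modeled (4-connected routing).
- No learned or data-fitted behavior models; no inner emotional or
  preference states; patient value preferences enter only through the choice
  of value models, not as agent state.
- Policy *optimization* is out of scope — `policy_sweep` enumerates a given
  list; it does not search.
- The event vocabulary is fixed; extending it requires touching protocol
  validation.
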