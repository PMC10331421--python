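# wardsim

A stochastic multi-agent simulation of a dementia-care nursing home, together
with an **Ethical Compliance Quantification (ECQ)** layer that turns simulation
run protocols into numerical scores on ethical value dimensions and compares
assistive-technology policies quantitatively.

It is intended for people who design or assess intelligent assistive
technologies (IAT) — here, a smart watch that detects when a resident has lost
orientation and prompts them with direction cues — and who want to explore, *in
silico*, how design choices such as "how many failed cues before we alert a
caregiver?" trade off against each other under different operationalizations
of values like safety and fairness.

## The model

The world is a 2D ward: a grid of walkable cells with named destinations
(resident rooms, lounge, dining) and nurse stations. Agents move in continuous
coordinates on this grid; routing is shortest-path over the 4-connected
walkable cells.

**Residents** walk between destinations on a cyclic activity schedule, with
per-tick step lengths drawn from a truncated normal
`max(0, N(mean_step, sd_step))`. At every en-route tick an oriented resident
becomes disoriented with probability `dis_level`; a disoriented resident
wanders as a correlated random walk (heading perturbed uniformly in ±90° each
tick, walls repel) until a cue succeeds, a nurse delivers them to their
destination, or they spontaneously reorient (probability `reorient_prob` per
tick).

**The smart watch** detects an ongoing disorientation with per-tick
probability `p_detect`, then issues cues every `cue_cooldown` ticks, each
restoring orientation with probability `p_cue_success`. Its **policy** is the
escalation rule `Nhelp`: after `Nhelp` failed cues it calls a nurse
(`Nhelp = 0` calls immediately upon detection). Baseline policies: *Nurse
Only* (no watch; nurses must discover wandering residents within a discovery
radius) and *No Help* (nobody intervenes).

**Nurses** idle at their station (doing all other caregiving), respond to
calls at walking speed, and escort the found resident to their destination at
the resident's (slower) guided pace.

Every run produces a **run protocol**: the per-tick state of every agent plus
the ordered event log (`DISORIENT`, `DETECT`, `CUE_FAIL`, `NURSE_CALLED`,
`GUIDE_END`, ...). Protocols are the sole input to all value models.

## Value models (ECQ)

For a run protocol with horizon `T`:

- `safety_original(p)` = (ticks disoriented) / `T` — a first, *implausible*
  operationalization: it counts time spent safely escorted by a nurse as
  unsafe. It is shipped deliberately, because comparing it across policies is
  what exposes the mistake.
- `safety_refined(p)` = (ticks disoriented **and** unguided) / `T`.
- `fairness(p)` = (nurse ticks responding or guiding) / (`n_nurses` × `T`) —
  the share of caregiver time lost to route guidance; its complement is time
  available for other forms of care.
- `efficiency(leg)` = straight-line distance / distance travelled for a
  completed walk, and `fairness_quotient(e_a, e_b) = min/max`, 1 when two
  stakeholders experience equal efficiency.

Safety and fairness are *violation* scores (0 = fully compliant); efficiency
and the fairness quotient are *compliance* scores (1 = optimal).
`policy_sweep` runs every policy with paired seeds and aggregates the score
matrices; `count_requirement` counts how often a qualitative requirement is
observed or violated across runs.

## Worked example

```bash
wardsim demo --out-dir demo_out --seed 0 --runs 30
```

generates the demo ward, draws wandering trajectories across increasing
`dis_level` values, runs the six-policy sweep (Nhelp ∈ {0, 1, 3, 5}, Nurse
Only, No Help; 30 paired-seed runs each) and prints the per-policy mean
scores:

```
  Nhelp=0: {'safety_original': '0.2191', 'safety_refined': '0.0898', 'fairness': '0.2218'}
  Nhelp=1: {'safety_original': '0.2061', 'safety_refined': '0.1083', 'fairness': '0.1686'}
  Nhelp=3: {'safety_original': '0.1897', 'safety_refined': '0.1328', 'fairness': '0.0978'}
  Nhelp=5: {'safety_original': '0.1911', 'safety_refined': '0.1595', 'fairness': '0.0543'}
  Nurse Only: {'safety_original': '0.3217', 'safety_refined': '0.2306', 'fairness': '0.1428'}
  No Help: {'safety_original': '0.6139', 'safety_refined': '0.6139', 'fairness': '0.0000'}
```

Read downward in `safety_refined`: calling a nurse immediately (Nhelp=0,
0.090) is safest; every extra tolerated cue failure adds unguided wandering
time; having no watch at all (Nurse Only, 0.231) is the least safe strategy
apart from leaving residents unattended (No Help, 0.614). `fairness` moves
the other way — waiting longer before calling saves caregiver time — which is
the safety/fairness trade-off in numbers. And `safety_original` *inverts* the
smart-watch ranking (0.219 at Nhelp=0 vs 0.191 at Nhelp=5): because it counts
escorted time as unsafe, it rewards policies that call nurses rarely. The
box-plot figure (`demo_out/score_boxplots.png`) makes the inversion visible
at a glance, which is exactly how ECQ surfaces a bad value operationalization.

The same pieces are available programmatically:

```python
from wardsim import demo_config, policy_sweep, demo_policies
from wardsim.ecq import resolve_value_models

models = resolve_value_models(["safety_original", "safety_refined", "fairness"])
result = policy_sweep(demo_config(), demo_policies(), 200, models, base_seed=0)
print(result.summary())
```

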