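"""Ethical Compliance Quantification: run protocols -> value scores.

A value model maps one run protocol to a score in [0, 1].  Polarity is
explicit: *violation* models (safety, guidance fairness) read 0 as fully
compliant, *compliance* models (efficiency, fairness quotient) read 1 as
optimal.  The two safety operationalizations deliberately coexist:

safety_original   fraction of ticks a patient is disoriented, regardless of
                  whether a nurse is escorting them.  Implausible on
                  reflection — escorted time is safe — and kept so the
                  implausibility can be demonstrated and discussed.
safety_refined    fraction of ticks disoriented while *not* nurse-guided.

fairness_guidance is the share of total caregiver duty time consumed by
responding to and guiding patients; its complement is the time left for all
other caregiving.  Efficiency of a completed leg is the ratio of straight-line
distance to distance travelled, and the fairness quotient compares two
stakeholders' efficiencies (1 = equal).

``ecq_evaluate`` scores a set of same-condition runs under a list of value
models; ``policy_sweep`` repeats that across assistive policies with paired
base seeds, which is what makes small policy contrasts detectable with a few
hundred runs per arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .agents import NurseTask, Policy
from .engine import SimConfig, completed_legs, iter_batch
from .errors import (
    DegenerateLegError,
    EmptySampleError,
    HeterogeneousRunsError,
    UndefinedQuotientError,
    UndefinedScoreError,
    UnknownPatientError,
)
from .protocol import ORI_CODE, RunProtocol, TASK_CODE
from .world import Position, path_length, straight_line_distance

VIOLATION = "violation"  # 0 = fully compliant
COMPLIANCE = "compliance"  # 1 = optimal


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, float(x)))


def _patient_mask(protocol: RunProtocol, patient_id: str) -> np.ndarray:
    if patient_id not in protocol.patient_ids:
        raise UnknownPatientError(
            f"no patient {patient_id!r} in protocol (has {protocol.patient_ids})"
        )
    return protocol.agent_mask(patient_id)


# ---------------------------------------------------------------------------
# Patient-level scores


def safety_original(protocol: RunProtocol, patient_id: str) -> float:
    """Violation score: fraction of ticks disoriented, guided or not."""
    mask = _patient_mask(protocol, patient_id)
    dis = protocol.states["ori"][mask] == ORI_CODE["D"]
    return _clamp01(dis.sum() / protocol.horizon)


def safety_refined(protocol: RunProtocol, patient_id: str) -> float:
    """Violation score: fraction of ticks disoriented while unguided."""
    mask = _patient_mask(protocol, patient_id)
    dis = protocol.states["ori"][mask] == ORI_CODE["D"]
    unguided = protocol.states["guide"][mask] == 0
    return _clamp01((dis & unguided).sum() / protocol.horizon)


def fairness_guidance(protocol: RunProtocol) -> float:
    """Violation score: share of caregiver duty time lost to route guidance.

    Counts nurse ticks spent responding or guiding over total nurse duty
    ticks (n_nurses x horizon); the complement is time available for other
    caregiving.  Undefined without nurses.
    """
    nurse_ids = protocol.nurse_ids
    if not nurse_ids:
        raise UndefinedScoreError("fairness_guidance is undefined with 0 nurses")
    task = protocol.states["task"]
    busy = (task == TASK_CODE["S"]) | (task == TASK_CODE["G"])
    return _clamp01(busy.sum() / (len(nurse_ids) * protocol.horizon))


def efficiency(trajectory: Sequence[Position]) -> float:
    """Compliance score for one completed leg: straight-line / travelled."""
    if len(trajectory) < 2:
        raise DegenerateLegError("a leg needs at least 2 positions")
    travelled = path_length(trajectory)
    if travelled <= 0.0:
        raise DegenerateLegError("zero travelled distance")
    return _clamp01(straight_line_distance(trajectory[0], trajectory[-1]) / travelled)


def fairness_quotient(eff_a: float, eff_b: float) -> float:
    """Compliance score comparing two efficiencies; 1 iff equal. Symmetric."""
    if eff_a <= 0.0 or eff_b <= 0.0:
        raise UndefinedQuotientError("fairness quotient needs efficiencies in (0, 1]")
    return _clamp01(min(eff_a, eff_b) / max(eff_a, eff_b))


def leg_trajectory(protocol: RunProtocol, leg) -> list[Position]:
    """Recorded positions of one completed leg, including the start point."""
    mask = protocol.agent_mask(leg.patient_id)
    t = protocol.states["t"][mask]
    xs = protocol.states["x"][mask]
    ys = protocol.states["y"][mask]
    sel = (t > leg.start_tick) & (t <= leg.end_tick)
    points = [Position(float(x), float(y)) for x, y in zip(xs[sel], ys[sel])]
    if leg.start_tick >= 0:
        at_start = t == leg.start_tick
        start = [Position(float(xs[at_start][0]), float(ys[at_start][0]))]
    else:
        start = []  # tick 0 already reflects one step from the start point
    return start + points


def run_efficiency(protocol: RunProtocol) -> float:
    """Mean leg efficiency over all completed legs of a run (0 if none)."""
    scores = []
    for leg in completed_legs(protocol):
        traj = leg_trajectory(protocol, leg)
        if len(traj) >= 2 and path_length(traj) > 0.0:
            scores.append(efficiency(traj))
    if not scores:
        return 0.0
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Value models


@dataclass(frozen=True)
class ValueModel:
    """A named scoring function protocol -> [0, 1] with explicit polarity.

    ``patient_fn``, when present, exposes the per-patient scores behind the
    run-level aggregate (kept for distributional analysis).
    """

    name: str
    polarity: str
    score_fn: Callable[[RunProtocol], float]
    patient_fn: Callable[[RunProtocol, str], float] | None = None

    def __call__(self, protocol: RunProtocol) -> float:
        return _clamp01(self.score_fn(protocol))


def _aggregate(values: Sequence[float], how: str) -> float:
    return float(max(values)) if how == "max" else float(np.mean(values))


def builtin_value_models(aggregate: str = "mean") -> dict[str, ValueModel]:
    """The shipped value models; per-run safety aggregates over patients."""
    if aggregate not in ("mean", "max"):
        raise ValueError(f"aggregate must be 'mean' or 'max', got {aggregate!r}")

    def run_orig(p: RunProtocol) -> float:
        return _aggregate([safety_original(p, pid) for pid in p.patient_ids], aggregate)

    def run_ref(p: RunProtocol) -> float:
        return _aggregate([safety_refined(p, pid) for pid in p.patient_ids], aggregate)

    return {
        "safety_original": ValueModel(
            "safety_original", VIOLATION, run_orig, safety_original
        ),
        "safety_refined": ValueModel(
            "safety_refined", VIOLATION, run_ref, safety_refined
        ),
        "fairness": ValueModel("fairness", VIOLATION, fairness_guidance),
        "efficiency": ValueModel("efficiency", COMPLIANCE, run_efficiency),
    }


def resolve_value_models(names: Iterable[str]) -> list[ValueModel]:
    """Look up built-in value models by name (accepts safety_* shorthands)."""
    registry = builtin_value_models()
    registry["fairness_guidance"] = registry["fairness"]
    models = []
    for name in names:
        if name not in registry:
            raise KeyError(
                f"unknown value model {name!r}; known: {sorted(set(registry))}"
            )
        models.append(registry[name])
    return models


# ---------------------------------------------------------------------------
# Qualitative requirements


class RequirementReport(NamedTuple):
    """Counts of a qualitative requirement across runs.

    The predicate returns True where the requirement is observed, False where
    it is violated, and None where it does not apply to that run.
    """

    n_runs: int
    observed: int
    violated: int
    observed_fraction: float
    violated_fraction: float


def count_requirement(
    protocols: Sequence[RunProtocol],
    predicate: Callable[[RunProtocol], bool | None],
) -> RequirementReport:
    """Evaluate a qualitative requirement run by run and count the outcomes."""
    if not protocols:
        raise EmptySampleError("count_requirement needs at least one protocol")
    observed = violated = 0
    for p in protocols:
        outcome = predicate(p)
        if outcome is True:
            observed += 1
        elif outcome is False:
            violated += 1
    n = len(protocols)
    return RequirementReport(n, observed, violated, observed / n, violated / n)


# ---------------------------------------------------------------------------
# Aggregation across runs and policies


@dataclass
class ECQResult:
    """Per-policy score matrices (runs x value models) with provenance."""

    scores: dict[str, pd.DataFrame]  # label -> DataFrame(index=seed, cols=models)
    polarities: dict[str, str]
    provenance: dict[str, dict] = field(default_factory=dict)
    patient_scores: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def policy_labels(self) -> list[str]:
        return list(self.scores)

    def matrix(self, label: str) -> pd.DataFrame:
        return self.scores[label]

    def mean(self, label: str, model: str) -> float:
        return float(self.scores[label][model].mean())

    def summary(self) -> pd.DataFrame:
        """mean/median/quartiles/min/max per policy per value model."""
        rows = []
        for label, df in self.scores.items():
            for model in df.columns:
                s = df[model]
                rows.append(
                    {
                        "policy": label,
                        "value": model,
                        "polarity": self.polarities[model],
                        "mean": s.mean(),
                        "median": s.median(),
                        "q1": s.quantile(0.25),
                        "q3": s.quantile(0.75),
                        "min": s.min(),
                        "max": s.max(),
                        "n_runs": len(s),
                    }
                )
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        """One row per run x value model: policy, seed, value, score, polarity."""
        rows = []
        for label, df in self.scores.items():
            long = df.reset_index().melt(
                id_vars="seed", var_name="value", value_name="score"
            )
            long.insert(0, "policy", label)
            rows.append(long)
        out = pd.concat(rows, ignore_index=True)
        out["polarity"] = out["value"].map(self.polarities)
        return out[["policy", "seed", "value", "score", "polarity"]]

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def summary_document(self) -> dict:
        doc = {"policies": {}}
        for label, df in self.scores.items():
            doc["policies"][label] = {
                "n_runs": int(len(df)),
                "values": {
                    model: {
                        "polarity": self.polarities[model],
                        "mean": float(df[model].mean()),
                        "median": float(df[model].median()),
                        "q1": float(df[model].quantile(0.25)),
                        "q3": float(df[model].quantile(0.75)),
                        "min": float(df[model].min()),
                        "max": float(df[model].max()),
                    }
                    for model in df.columns
                },
                **self.provenance.get(label, {}),
            }
        return doc

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_document(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _score_stream(
    protocols: Iterable[RunProtocol],
    value_models: Sequence[ValueModel],
    label: str,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    seeds: list[int] = []
    rows: list[list[float]] = []
    patient_rows: list[dict] = []
    digest = None
    for p in protocols:
        if digest is None:
            digest = p.config_digest
        elif p.config_digest != digest:
            raise HeterogeneousRunsError(
                "protocols come from different configurations; "
                "ECQ compares like with like"
            )
        seeds.append(p.seed)
        rows.append([model(p) for model in value_models])
        for model in value_models:
            if model.patient_fn is not None:
                for pid in p.patient_ids:
                    patient_rows.append(
                        {
                            "seed": p.seed,
                            "patient": pid,
                            "value": model.name,
                            "score": model.patient_fn(p, pid),
                        }
                    )
    if digest is None:
        raise EmptySampleError("no protocols to evaluate")
    matrix = pd.DataFrame(
        rows, columns=[m.name for m in value_models], index=pd.Index(seeds, name="seed")
    )
    patient_df = pd.DataFrame(patient_rows)
    prov = {"config_digest": digest, "seeds": seeds}
    return matrix, patient_df, prov


def ecq_evaluate(
    protocols: Iterable[RunProtocol],
    value_models: Sequence[ValueModel],
    label: str = "condition",
) -> ECQResult:
    """Score a set of same-condition run protocols under the given models.

    Protocols must share a config digest; mixing conditions raises
    HeterogeneousRunsError.  An empty model list yields an empty matrix.
    """
    matrix, patient_df, prov = _score_stream(protocols, value_models, label)
    return ECQResult(
        scores={label: matrix},
        polarities={m.name: m.polarity for m in value_models},
        provenance={label: prov},
        patient_scores={label: patient_df},
    )


def policy_sweep(
    config: SimConfig,
    policies: Sequence[Policy],
    n_runs: int,
    value_models: Sequence[ValueModel],
    base_seed: int | None = None,
) -> ECQResult:
    """Run and score every policy under paired seeds.

    Each policy arm runs ``n_runs`` simulations seeded base_seed + i, so arm
    contrasts share their random draws up to the first policy-dependent
    branch (a variance-reduction pairing).  Runs are generated and scored
    one at a time; protocols are not retained.
    """
    if not policies:
        raise EmptySampleError("policy_sweep needs at least one policy")
    base_seed = config.seed if base_seed is None else base_seed
    scores: dict[str, pd.DataFrame] = {}
    provenance: dict[str, dict] = {}
    patient_scores: dict[str, pd.DataFrame] = {}
    for policy in policies:
        cfg = replace(config, policy=policy)
        label = policy.label
        matrix, patient_df, prov = _score_stream(
            iter_batch(cfg, n_runs, base_seed), value_models, label
        )
        scores[label] = matrix
        provenance[label] = prov
        patient_scores[label] = patient_df
    return ECQResult(
        scores=scores,
        polarities={m.name: m.polarity for m in value_models},
        provenance=provenance,
        patient_scores=patient_scores,
    )
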