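"""Synthetic trial-level behavioral data with known logit structure.

The generator emulates the layout of the deposited behavioral data so the
preprocessing and mixed-model stages are fully testable without any
download: one row per participant x trial with condition, block, stimulus
identity, role, category, repetition count, a binary ``correct`` score
and a reaction time.

Correctness is Bernoulli with a role x condition logit structure,

    logit P(correct) = intercept(role, condition)
                       + slope(role, condition) * (repetition - 1)
                       + u_participant,      u ~ Normal(0, sd^2)

with the linear predictor capped at +-10 so saturated configurations stay
finite.  Reaction times are truncated log-normal draws; they exist solely
to exercise the exclusion rules and are never analyzed.  Ground-truth
parameters and per-participant latent intercepts are stored losslessly
alongside the table.

The default parameters qualitatively mimic the empirical pattern —
prototypes easiest, then rule-followers, then exceptions, with a delayed-
condition advantage for exceptions that grows with repetition — and are
illustrative, not a calibration to any dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import SequenceConfig, generate_learning_sequence, generate_test_sequence
from .stimuli import StimulusSet, build_type3_structure

__all__ = [
    "BehavioralGenConfig",
    "GeneratedDataset",
    "generate_participants",
    "inject_exclusion_cases",
    "DEFAULT_INTERCEPTS",
    "DEFAULT_SLOPES",
]

LOGIT_CAP = 10.0

DEFAULT_INTERCEPTS: Mapping[tuple[str, str], float] = {
    ("prototype", "early"): 1.3, ("prototype", "delayed"): 1.3,
    ("rule_follower", "early"): 0.8, ("rule_follower", "delayed"): 0.7,
    ("exception", "early"): -0.6, ("exception", "delayed"): -0.2,
}

DEFAULT_SLOPES: Mapping[tuple[str, str], float] = {
    ("prototype", "early"): 0.030, ("prototype", "delayed"): 0.030,
    ("rule_follower", "early"): 0.025, ("rule_follower", "delayed"): 0.025,
    ("exception", "early"): 0.010, ("exception", "delayed"): 0.040,
}


@dataclass(frozen=True)
class BehavioralGenConfig:
    """Ground-truth parameters of the behavioral generator."""

    n_participants: int = 40  # per condition
    intercepts: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    slopes: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES))
    participant_sd: float = 0.5
    rt_meanlog: float = np.log(0.7)
    rt_sdlog: float = 0.35
    rt_bounds: tuple[float, float] = (0.2, 1.95)
    include_test_block: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.participant_sd < 0 or self.rt_sdlog < 0:
            raise ValueError("standard deviations must be nonnegative")
        keys = {(r, c) for r in ("prototype", "rule_follower", "exception")
                for c in ("early", "delayed")}
        if set(self.intercepts) != keys or set(self.slopes) != keys:
            raise ValueError("intercepts and slopes must cover every (role, condition) cell")


@dataclass(frozen=True)
class GeneratedDataset:
    """A behavioral table plus the parameters that generated it."""

    table: pd.DataFrame
    config: BehavioralGenConfig
    participant_intercepts: Mapping[str, float]
    planted: Mapping[str, tuple] = field(default_factory=dict)

    def truth_json(self) -> str:
        return json.dumps({
            "intercepts": {f"{r}|{c}": v for (r, c), v in self.config.intercepts.items()},
            "slopes": {f"{r}|{c}": v for (r, c), v in self.config.slopes.items()},
            "participant_sd": self.config.participant_sd,
            "participant_intercepts": dict(self.participant_intercepts),
        }, indent=2)


def _truncated_lognormal(rng: np.random.Generator, n: int, meanlog: float, sdlog: float,
                         bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    out = np.empty(n)
    remaining = np.arange(n)
    for _ in range(1000):
        draw = rng.lognormal(meanlog, sdlog, size=remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
        if remaining.size == 0:
            return out
    out[remaining] = np.clip(rng.lognormal(meanlog, sdlog, size=remaining.size), lo, hi)
    return out


def generate_participants(config: BehavioralGenConfig | None = None,
                          stimulus_set: StimulusSet | None = None) -> GeneratedDataset:
    """Simulate trial tables for ``n_participants`` per condition.

    Each participant gets their own seeded learning sequence (and test
    sequence when enabled), a latent intercept, Bernoulli correctness
    from the logit structure, and truncated log-normal reaction times.
    Deterministic under the config seed.
    """
    config = config or BehavioralGenConfig()
    stimulus_set = stimulus_set or build_type3_structure()
    root = np.random.SeedSequence(config.seed)
    rows = []
    intercepts: dict[str, float] = {}
    pid_no = 0
    for condition in ("early", "delayed"):
        for i in range(config.n_participants):
            pid_no += 1
            pid = f"{condition[0].upper()}{pid_no:03d}"
            child = np.random.default_rng(root.spawn(1)[0])
            u = float(child.normal(0.0, config.participant_sd))
            intercepts[pid] = u
            seq_seed = int(child.integers(0, 2**31 - 1))
            trials = list(generate_learning_sequence(
                stimulus_set, SequenceConfig(condition, seed=seq_seed)))
            if config.include_test_block:
                test = generate_test_sequence(stimulus_set, seed=seq_seed + 1)
                offset = len(trials)
                trials += [t for t in test]
            rep_count: dict[str, int] = {}
            n = len(trials)
            rts = _truncated_lognormal(child, n, config.rt_meanlog, config.rt_sdlog,
                                       config.rt_bounds)
            unif = child.uniform(size=n)
            running_index = 0
            for t, rt, uu in zip(trials, rts, unif):
                running_index += 1
                s = stimulus_set[t.stimulus_id]
                rep_count[s.role] = rep_count.get(s.role, 0) + 1
                rep = rep_count[s.role]
                eta = (config.intercepts[(s.role, condition)]
                       + config.slopes[(s.role, condition)] * (rep - 1) + u)
                eta = float(np.clip(eta, -LOGIT_CAP, LOGIT_CAP))
                p = 1.0 / (1.0 + np.exp(-eta))
                rows.append((pid, condition, t.block, running_index, t.stimulus_id,
                             s.role, s.category, t.phase, rep, int(uu < p), float(rt)))
    table = pd.DataFrame(rows, columns=[
        "participant_id", "condition", "block", "trial_index", "stimulus_id",
        "role", "category", "phase", "repetition", "correct", "rt",
    ])
    return GeneratedDataset(table=table, config=config, participant_intercepts=intercepts)


def inject_exclusion_cases(dataset: GeneratedDataset,
                           accuracy_violators: Sequence[str] = (),
                           rt_violators: Sequence[str] = (),
                           out_of_range_trials: Mapping[str, Sequence[int]] | None = None,
                           ) -> GeneratedDataset:
    """Deterministically plant pathologies that the exclusion rules must
    catch, tagged so filter output can be checked exactly.

    * ``accuracy_violators`` — participants whose every response is made
      incorrect (accuracy 0 in every block, violating the 0.75 rule);
    * ``rt_violators`` — participants whose first 25% of trials get a
      2.5 s reaction time (violating the 20% out-of-range rule);
    * ``out_of_range_trials`` — individual (participant -> trial indices)
      whose reaction time is set to 0.05 s, below the trial-level floor.
    """
    table = dataset.table.copy()
    ids = set(table["participant_id"])
    for group in (accuracy_violators, rt_violators, (out_of_range_trials or {}).keys()):
        unknown = set(group) - ids
        if unknown:
            raise KeyError(f"unknown participants {sorted(unknown)}")

    for pid in accuracy_violators:
        table.loc[table["participant_id"] == pid, "correct"] = 0
    for pid in rt_violators:
        rows = table.index[table["participant_id"] == pid]
        n_bad = int(np.ceil(0.25 * len(rows)))
        table.loc[rows[:n_bad], "rt"] = 2.5
    planted_trials = []
    for pid, indices in (out_of_range_trials or {}).items():
        for idx in indices:
            mask = (table["participant_id"] == pid) & (table["trial_index"] == idx)
            if not mask.any():
                raise KeyError(f"participant {pid} has no trial {idx}")
            table.loc[mask, "rt"] = 0.05
            planted_trials.append((pid, int(idx)))
    planted = {
        "accuracy_violators": tuple(accuracy_violators),
        "rt_violators": tuple(rt_violators),
        "out_of_range_trials": tuple(planted_trials),
    }
    return replace(dataset, table=table, planted=planted)
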