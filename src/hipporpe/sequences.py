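"""Early- and delayed-condition learning sequences and the common test
sequence.

Both conditions present 144 learning trials in three 48-trial blocks with
a 2:1:1 ratio of prototype to rule-follower to exception trials overall
(72 : 36 : 36).  In the *early* condition every block mixes all three
roles (24 P, 12 R, 12 E per block); in the *delayed* condition exceptions
are withheld from block 1 (32 P, 16 R) and introduced from trial 49
onward (blocks 2–3: 20 P, 10 R, 18 E each), holding the role totals
fixed.  The first eight trials of block 1 are prototypes in both
conditions, so the learner sees every feature value before any irregular
item.  The 48-trial test sequence presents 16 trials of each role and is
identical in composition across conditions.

Checkpoint schedules give the trial indices at which a training run is
paused and the network is probed with all ten stimuli; the delayed
schedule samples densely around the introduction of the exceptions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .stimuli import ROLES, StimulusSet

__all__ = [
    "Trial",
    "SequenceConfig",
    "TrialSequence",
    "SequenceError",
    "generate_learning_sequence",
    "generate_test_sequence",
    "checkpoint_schedule",
    "EARLY_CHECKPOINTS",
    "DELAYED_CHECKPOINTS",
]

ROLE_TOTALS = {"prototype": 72, "rule_follower": 36, "exception": 36}

EARLY_BLOCKS = ({"prototype": 24, "rule_follower": 12, "exception": 12},) * 3
DELAYED_BLOCKS = (
    {"prototype": 32, "rule_follower": 16, "exception": 0},
    {"prototype": 20, "rule_follower": 10, "exception": 18},
    {"prototype": 20, "rule_follower": 10, "exception": 18},
)

EARLY_CHECKPOINTS = (12, 36, 48, 72, 96, 120, 144)
DELAYED_CHECKPOINTS = (24, 48, 60, 72, 84, 96, 120, 144)

PROTOTYPE_PREFIX = 8


class SequenceError(ValueError):
    """Raised when a sequence composition is infeasible."""


@dataclass(frozen=True)
class Trial:
    index: int  # 1-based position within the phase
    stimulus_id: str
    block: int | str  # 1..3 for learning, "test" for test trials
    phase: str  # "learning" | "test"


@dataclass(frozen=True)
class SequenceConfig:
    condition: str  # "early" | "delayed"
    seed: int
    block_composition: tuple[Mapping[str, int], ...] = field(default=None)  # type: ignore[assignment]
    prototype_prefix: int = PROTOTYPE_PREFIX

    def __post_init__(self) -> None:
        if self.condition not in ("early", "delayed"):
            raise SequenceError(f"unknown condition {self.condition!r}")
        if self.block_composition is None:
            default = EARLY_BLOCKS if self.condition == "early" else DELAYED_BLOCKS
            object.__setattr__(self, "block_composition", default)
        totals = {role: sum(b.get(role, 0) for b in self.block_composition) for role in ROLES}
        if totals != ROLE_TOTALS:
            raise SequenceError(
                f"role totals must be {ROLE_TOTALS} across blocks, got {totals}"
            )
        for i, block in enumerate(self.block_composition, start=1):
            if sum(block.values()) != 48:
                raise SequenceError(f"block {i} composition must sum to 48 trials")
        if self.block_composition[0].get("prototype", 0) < self.prototype_prefix:
            raise SequenceError("block 1 cannot satisfy the prototype-only prefix")


@dataclass(frozen=True)
class TrialSequence:
    trials: tuple[Trial, ...]
    config: SequenceConfig | None = None

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def stimulus_ids(self) -> tuple[str, ...]:
        return tuple(t.stimulus_id for t in self.trials)

    def to_csv(self, path, stimulus_set: StimulusSet) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["trial_index", "block", "phase", "stimulus_id", "role", "category", "encoding"]
            )
            for t in self.trials:
                s = stimulus_set[t.stimulus_id]
                writer.writerow(
                    [t.index, t.block, t.phase, t.stimulus_id, s.role, s.category,
                     "".join(map(str, s.encoding.tolist()))]
                )


def _balanced_members(members: Sequence[str], n: int, rng: np.random.Generator,
                      offset: int = 0) -> list[str]:
    """n stimulus ids drawn from ``members`` as evenly as possible (counts
    differ by at most 1); ``offset`` rotates which members get the extra
    trial so that remainders alternate across blocks."""
    k = len(members)
    base, extra = divmod(n, k)
    counts = {m: base for m in members}
    for j in range(extra):
        counts[members[(offset + j) % k]] += 1
    pool = [m for m, c in counts.items() for _ in range(c)]
    rng.shuffle(pool)
    return pool


def generate_learning_sequence(stimulus_set: StimulusSet, config: SequenceConfig) -> TrialSequence:
    """Generate one seeded 144-trial learning sequence.

    Within each block the role composition is fixed by the condition, the
    order is a seeded random permutation, members of a role appear equally
    often (±1, with remainders rotated across blocks), and trials 1–8 are
    prototypes.  Delayed sequences therefore contain no exception before
    trial 49.
    """
    rng = np.random.default_rng(config.seed)
    members = {role: [s.id for s in stimulus_set.by_role(role)] for role in ROLES}

    trials: list[Trial] = []
    index = 1
    for block_no, comp in enumerate(config.block_composition, start=1):
        pool: list[str] = []
        for role in ROLES:
            pool.extend(
                _balanced_members(members[role], comp.get(role, 0), rng, offset=block_no - 1)
            )
        rng.shuffle(pool)
        if block_no == 1 and config.prototype_prefix:
            # move a balanced draw of prototypes to the front of block 1
            prefix: list[str] = []
            proto_ids = members["prototype"]
            want = {m: 0 for m in proto_ids}
            for j in range(config.prototype_prefix):
                want[proto_ids[j % len(proto_ids)]] += 1
            rest = []
            for sid in pool:
                if sid in want and want[sid] > 0:
                    prefix.append(sid)
                    want[sid] -= 1
                else:
                    rest.append(sid)
            rng.shuffle(prefix)
            pool = prefix + rest
        for sid in pool:
            trials.append(Trial(index=index, stimulus_id=sid, block=block_no, phase="learning"))
            index += 1
    return TrialSequence(trials=tuple(trials), config=config)


def generate_test_sequence(stimulus_set: StimulusSet, seed: int) -> TrialSequence:
    """48-trial test sequence: 16 trials per role in seeded random order,
    identical composition regardless of condition."""
    rng = np.random.default_rng(seed)
    pool: list[str] = []
    for role in ROLES:
        pool.extend(_balanced_members([s.id for s in stimulus_set.by_role(role)], 16, rng))
    rng.shuffle(pool)
    trials = tuple(
        Trial(index=i, stimulus_id=sid, block="test", phase="test")
        for i, sid in enumerate(pool, start=1)
    )
    return TrialSequence(trials=trials, config=None)


def checkpoint_schedule(condition: str) -> tuple[int, ...]:
    """Trial indices at which the network is probed during learning."""
    if condition == "early":
        return EARLY_CHECKPOINTS
    if condition == "delayed":
        return DELAYED_CHECKPOINTS
    raise SequenceError(f"unknown condition {condition!r}")
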