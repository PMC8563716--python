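"""Shepard–Hovland–Jenkins Type III rule-plus-exception stimulus structure.

Ten flower stimuli are defined on four binary feature dimensions (outer
petal colour, outer petal shape, inner petal shape, central disc colour)
plus a binary category label.  The first three dimensions are diagnostic:
the Type III assignment makes category membership a simple rule on them for
eight of the ten stimuli, with one exception per category that sits closer
(in diagnostic Hamming distance) to the *opposite* category's prototype.
The fourth dimension is nondiagnostic — it carries no category information
but contributes to overall stimulus similarity, which is what makes the two
exceptions asymmetric (see :data:`DEFAULT_STRUCTURE`).

Stimulus roles, defined by diagnostic distance to the own-category
prototype triple:

* ``prototype`` — distance 0 (two per category, one per nondiagnostic value)
* ``rule_follower`` — distance 1
* ``exception`` — distance 2 from own prototype, distance 1 from the
  opposite prototype

Each stimulus is encoded for the network as a length-10 padded binary
vector: five unit pairs, one pair per dimension, with feature value 0
mapped to ``10`` and value 1 mapped to ``01`` so that the all-zero category
A prototype encodes ``1010101010``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "FeatureVector",
    "Stimulus",
    "StimulusSet",
    "StructureConfig",
    "StructureError",
    "DEFAULT_STRUCTURE",
    "CANONICAL_ORDER",
    "ROLES",
    "build_type3_structure",
    "encode",
    "decode",
    "pairwise_distance",
]

ROLES = ("prototype", "rule_follower", "exception")

#: Canonical stimulus order used by every similarity matrix: category A
#: then category B, within category prototype, prototype, rule-follower,
#: rule-follower, exception.
CANONICAL_ORDER = ("PA1", "PA2", "RA1", "RA2", "EA", "PB1", "PB2", "RB1", "RB2", "EB")


class StructureError(ValueError):
    """Raised when a requested category structure violates the Type III
    role-distance invariants."""


@dataclass(frozen=True)
class FeatureVector:
    """Binary feature values of one stimulus.

    ``d1``–``d3`` are the diagnostic dimensions, ``d4`` the nondiagnostic
    central-disc colour, and ``d5`` the category label (0 = A, 1 = B).
    ``d5`` is never free: it is determined by (d1, d2, d3) through the
    Type III assignment.
    """

    d1: int
    d2: int
    d3: int
    d4: int
    d5: int

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "d3", "d4", "d5"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")

    @property
    def diagnostic(self) -> tuple[int, int, int]:
        return (self.d1, self.d2, self.d3)

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.d1, self.d2, self.d3, self.d4, self.d5)


@dataclass(frozen=True)
class Stimulus:
    """One of the ten flower stimuli."""

    id: str
    role: str
    category: str
    features: FeatureVector

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.category not in ("A", "B"):
            raise ValueError(f"category must be 'A' or 'B', got {self.category!r}")

    @property
    def encoding(self) -> np.ndarray:
        """Length-10 padded binary encoding (see :func:`encode`)."""
        return encode(self)


@dataclass(frozen=True)
class StructureConfig:
    """Diagnostic-triple and nondiagnostic-value assignment for the ten
    stimuli.

    ``diagnostic`` maps stimulus id to its (d1, d2, d3) triple;
    ``nondiagnostic`` maps stimulus id to its d4 value.  The default
    (:data:`DEFAULT_STRUCTURE`) is one canonical Type III isomorph in which
    the category A exception shares its nondiagnostic value with its
    diagnostically nearest own-category rule-follower and prototype
    variant, while the category B exception does not — the asymmetry that
    drives the differing fate of the two exceptions.
    """

    diagnostic: Mapping[str, tuple[int, int, int]]
    nondiagnostic: Mapping[str, int]


DEFAULT_STRUCTURE = StructureConfig(
    diagnostic={
        "PA1": (0, 0, 0), "PA2": (0, 0, 0), "RA1": (0, 0, 1), "RA2": (0, 1, 0),
        "EA": (1, 1, 0),
        "PB1": (1, 1, 1), "PB2": (1, 1, 1), "RB1": (1, 0, 1), "RB2": (0, 1, 1),
        "EB": (1, 0, 0),
    },
    nondiagnostic={
        "PA1": 0, "PA2": 1, "RA1": 1, "RA2": 0, "EA": 0,
        "PB1": 0, "PB2": 1, "RB1": 1, "RB2": 0, "EB": 0,
    },
)


def _role_of(sid: str) -> str:
    return {"P": "prototype", "R": "rule_follower", "E": "exception"}[sid[0]]


def _category_of(sid: str) -> str:
    return sid[1]


@dataclass(frozen=True)
class StimulusSet:
    """The ten stimuli plus the structure configuration that produced them."""

    stimuli: tuple[Stimulus, ...]
    structure_config: StructureConfig = field(default=DEFAULT_STRUCTURE)

    def __iter__(self) -> Iterator[Stimulus]:
        return iter(self.stimuli)

    def __len__(self) -> int:
        return len(self.stimuli)

    def __getitem__(self, sid: str) -> Stimulus:
        for s in self.stimuli:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.stimuli)

    def by_role(self, role: str) -> tuple[Stimulus, ...]:
        return tuple(s for s in self.stimuli if s.role == role)

    def by_category(self, category: str) -> tuple[Stimulus, ...]:
        return tuple(s for s in self.stimuli if s.category == category)

    def encoding_matrix(self) -> np.ndarray:
        """10x10 0/1 matrix of encodings, rows in canonical order."""
        return np.stack([self[sid].encoding for sid in CANONICAL_ORDER])

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "stimuli": [
                {
                    "id": s.id,
                    "role": s.role,
                    "category": s.category,
                    "features": list(s.features.as_tuple()),
                    "encoding": "".join(map(str, s.encoding.tolist())),
                }
                for s in self.stimuli
            ]
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusSet":
        doc = json.loads(text)
        diagnostic = {}
        nondiagnostic = {}
        for rec in doc["stimuli"]:
            f = rec["features"]
            diagnostic[rec["id"]] = (f[0], f[1], f[2])
            nondiagnostic[rec["id"]] = f[3]
        return build_type3_structure(StructureConfig(diagnostic, nondiagnostic))

    def write_encoding_matrix(self, path) -> None:
        np.savetxt(path, self.encoding_matrix(), fmt="%d")


def build_type3_structure(config: StructureConfig | None = None) -> StimulusSet:
    """Build and validate the ten-stimulus Type III structure.

    Parameters
    ----------
    config
        Diagnostic-triple and nondiagnostic-value assignment; defaults to
        :data:`DEFAULT_STRUCTURE`.

    Raises
    ------
    StructureError
        If the assignment violates any role-distance invariant (prototype
        separation, rule-follower distance 1, exception distances 2/1) or
        the prototype d4 coverage requirement.
    """
    config = config or DEFAULT_STRUCTURE
    if set(config.diagnostic) != set(CANONICAL_ORDER):
        raise StructureError(
            f"diagnostic assignment must cover exactly {CANONICAL_ORDER}"
        )
    if set(config.nondiagnostic) != set(CANONICAL_ORDER):
        raise StructureError(
            f"nondiagnostic assignment must cover exactly {CANONICAL_ORDER}"
        )

    proto = {c: config.diagnostic[f"P{c}1"] for c in "AB"}
    if config.diagnostic["PA2"] != proto["A"] or config.diagnostic["PB2"] != proto["B"]:
        raise StructureError("the two prototypes of a category must share one diagnostic triple")
    if _hamming(proto["A"], proto["B"]) != 3:
        raise StructureError("category prototypes must differ in all three diagnostic dimensions")

    for sid in CANONICAL_ORDER:
        cat = _category_of(sid)
        own = _hamming(config.diagnostic[sid], proto[cat])
        opp = _hamming(config.diagnostic[sid], proto["B" if cat == "A" else "A"])
        role = _role_of(sid)
        if role == "prototype" and own != 0:
            raise StructureError(f"{sid}: prototype must match its category triple")
        if role == "rule_follower" and own != 1:
            raise StructureError(f"{sid}: rule-follower must be at diagnostic distance 1 "
                                 f"from its prototype (got {own})")
        if role == "exception" and (own != 2 or opp != 1):
            raise StructureError(f"{sid}: exception must be at diagnostic distance 2 from its "
                                 f"own and 1 from the opposite prototype (got {own}, {opp})")

    for c in "AB":
        d4s = {config.nondiagnostic[f"P{c}1"], config.nondiagnostic[f"P{c}2"]}
        if d4s != {0, 1}:
            raise StructureError(f"category {c} prototypes must cover both nondiagnostic values")

    stimuli = tuple(
        Stimulus(
            id=sid,
            role=_role_of(sid),
            category=_category_of(sid),
            features=FeatureVector(
                *config.diagnostic[sid],
                config.nondiagnostic[sid],
                0 if _category_of(sid) == "A" else 1,
            ),
        )
        for sid in CANONICAL_ORDER
    )
    return StimulusSet(stimuli=stimuli, structure_config=config)


def _hamming(a: Sequence[int], b: Sequence[int]) -> int:
    return sum(x != y for x, y in zip(a, b))


def encode(stimulus: Stimulus) -> np.ndarray:
    """Padded binary encoding: five unit pairs, one per dimension.

    Pair ``k`` (units 2k, 2k+1) one-hot codes dimension ``k+1``: value 0
    maps to ``10`` and value 1 to ``01``, so the all-zero category A
    prototype encodes ``1010101010``.
    """
    vec = np.zeros(10, dtype=np.int64)
    for k, v in enumerate(stimulus.features.as_tuple()):
        vec[2 * k + v] = 1
    return vec


def decode(vector: Sequence[int], stimulus_set: StimulusSet) -> Stimulus:
    """Inverse of :func:`encode` within a stimulus set.

    Raises ``KeyError`` if the vector does not encode any member.
    """
    arr = np.asarray(vector, dtype=np.int64)
    if arr.shape != (10,):
        raise ValueError("encoding must have length 10")
    for s in stimulus_set:
        if np.array_equal(s.encoding, arr):
            return s
    raise KeyError(f"no stimulus with encoding {arr.tolist()}")


def pairwise_distance(a: Stimulus, b: Stimulus, include_nondiagnostic: bool = False) -> int:
    """Hamming distance over the diagnostic dimensions d1–d3, or d1–d4
    when ``include_nondiagnostic`` is set."""
    n = 4 if include_nondiagnostic else 3
    return _hamming(a.features.as_tuple()[:n], b.features.as_tuple()[:n])


def no_single_dimension_separates(stimulus_set: StimulusSet) -> bool:
    """True when no single diagnostic dimension perfectly predicts category
    (the defining difference between Type III and Type I structures)."""
    for d in range(3):
        values = {}
        separates = True
        for s in stimulus_set:
            v = s.features.diagnostic[d]
            if v in values and values[v] != s.category:
                separates = False
                break
            values[v] = s.category
        if separates:
            return False
    return True
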