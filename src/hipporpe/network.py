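"""Rate-coded hippocampal autoencoder with trisynaptic and monosynaptic
pathways.

The network is the standard five-layer abstraction of the hippocampal
circuit: superficial entorhinal cortex (``EC_in``) feeds the trisynaptic
pathway (TSP: EC_in -> DG -> CA3 -> CA1) and the monosynaptic pathway
(MSP: EC_in -> CA1), CA1 drives deep entorhinal cortex (``EC_out``), and
EC_out feeds back both to CA1 and — via big-loop recurrence — to EC_in.
DG and CA3 are small-k winners-take-all layers (strong inhibition, sparse
codes, pattern separation); CA1 is denser and supports generalization.
TSP projections learn faster than MSP projections.

The model is trained as an autoencoder: each trial presents one stimulus
encoding to EC_in and the weights move so that EC_out reproduces it.
Learning is two-phase and error-driven, echoing theta-cycle learning in
hippocampus: an *expectation* phase settles with EC_out free, an
*outcome* phase settles with EC_out clamped to the true pattern, and each
projection's weights change by the difference of the two phases' Hebbian
coproducts plus a small soft-bounded Hebbian term.  At test the category
unit pair of the cue is blanked and the settled EC_out activity is read
out (:mod:`hipporpe.readout`), so correct categorization requires pattern
completion through the learned circuit.

Activation dynamics per settling cycle: each projection contributes a net
input normalized by its source layer's expected activity; hidden layers
pass their summed net input through a k-winners-take-all ramp (units below
the k-th/k+1-th midpoint threshold are silenced, the rest scale linearly
to the layer maximum); EC_out applies a logistic squash.  Activations
relax toward these targets with a fixed step size until convergence or
the cycle budget (80 cycles by default) is exhausted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import TrialSequence, checkpoint_schedule, SequenceConfig, generate_learning_sequence
from .stimuli import CANONICAL_ORDER, StimulusSet, build_type3_structure

__all__ = [
    "LayerSpec",
    "ProjectionSpec",
    "NetworkParams",
    "NetworkState",
    "TestSnapshot",
    "BatchEnsemble",
    "DynamicsError",
    "default_params",
    "init_network",
    "settle",
    "train_trial",
    "train_sequence",
    "test_items",
    "run_batches",
]

HIDDEN_LAYERS = ("DG", "CA3", "CA1")
LAYERS = ("EC_in", "DG", "CA3", "CA1", "EC_out")

#: The eight projections of the circuit, as (source, target, pathway).
PROJECTION_GRAPH = (
    ("EC_in", "DG", "TSP"),
    ("EC_in", "CA3", "TSP"),
    ("DG", "CA3", "TSP"),
    ("CA3", "CA1", "TSP"),
    ("EC_in", "CA1", "MSP"),
    ("CA1", "EC_out", "output"),
    ("EC_out", "CA1", "MSP"),
    ("EC_out", "EC_in", "bigloop"),
)


class DynamicsError(RuntimeError):
    """Raised when settling produces non-finite activations."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer: size, winner budget, and inhibition style.

    ``soft_inhibition`` selects a graded logistic competition (units below
    the k-WTA threshold are suppressed but not silenced) — the low-
    inhibition regime of CA1, which keeps its code distributed and
    overlapping.  Hard k-WTA (DG, CA3) silences everything below
    threshold.
    """

    name: str
    n_units: int
    k_active: int
    soft_inhibition: bool = False

    def __post_init__(self) -> None:
        if self.n_units <= 0 or not (0 < self.k_active <= self.n_units):
            raise ValueError(f"invalid layer spec {self}")


@dataclass(frozen=True)
class ProjectionSpec:
    source: str
    target: str
    pathway: str  # TSP | MSP | output | bigloop
    learning_rate: float
    strength_scale: float = 1.0
    rel_weight: float = 1.0  # relative mixing weight of this input at the target

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not (0.0 <= self.strength_scale <= 1.0):
            raise ValueError("strength_scale must be in [0, 1]")
        if self.rel_weight < 0:
            raise ValueError("rel_weight must be nonnegative")


@dataclass(frozen=True)
class NetworkParams:
    """Architecture and dynamics parameters.

    ``phase_schedule`` splits each training trial's settling cycles into
    (expectation, outcome) counts; the two must sum to
    ``n_settle_cycles``.  ``weight_init`` gives the (low, high) bounds of
    the uniform weight initialization.  ``hebb_fraction`` scales the
    Hebbian term relative to each projection's error-driven rate.
    """

    layers: tuple[LayerSpec, ...]
    projections: tuple[ProjectionSpec, ...]
    n_settle_cycles: int = 80
    phase_schedule: tuple[int, int] = (60, 20)
    weight_init: tuple[float, float] = (0.25, 0.75)
    hebb_fraction: float = 0.4
    competitive_hebb_fraction: float = 0.05
    step_size: float = 0.5
    ramp_sharpness: float = 0.3
    soft_temp: float = 0.3
    out_threshold: float = 0.3
    out_gain: float = 0.05
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_settle_cycles < 1:
            raise ValueError("n_settle_cycles must be >= 1")
        if sum(self.phase_schedule) != self.n_settle_cycles:
            raise ValueError("phase_schedule must partition n_settle_cycles")
        names = [l.name for l in self.layers]
        if sorted(names) != sorted(LAYERS):
            raise ValueError(f"layers must be exactly {LAYERS}")
        spec = {l.name: l for l in self.layers}
        frac = {n: spec[n].k_active / spec[n].n_units for n in HIDDEN_LAYERS}
        if not (frac["DG"] < frac["CA3"] < frac["CA1"]):
            raise ValueError("activity fractions must be ordered DG < CA3 < CA1")
        edges = sorted((p.source, p.target) for p in self.projections)
        if edges != sorted((s, t) for s, t, _ in PROJECTION_GRAPH):
            raise ValueError("projection graph must match the 8-edge hippocampal circuit")
        tsp = [p.learning_rate for p in self.projections if p.pathway == "TSP"]
        msp = [p.learning_rate for p in self.projections if p.pathway in ("MSP", "output")]
        if min(tsp) <= max(msp):
            raise ValueError("every TSP learning rate must exceed every MSP learning rate")

    @property
    def layer(self) -> Mapping[str, LayerSpec]:
        return {l.name: l for l in self.layers}

    def to_yaml(self) -> str:
        import yaml

        doc = {
            "layers": [vars(l) | {} for l in self.layers],
            "projections": [vars(p) | {} for p in self.projections],
            "n_settle_cycles": self.n_settle_cycles,
            "phase_schedule": list(self.phase_schedule),
            "weight_init": list(self.weight_init),
            "hebb_fraction": self.hebb_fraction,
            "step_size": self.step_size,
            "ramp_sharpness": self.ramp_sharpness,
            "out_threshold": self.out_threshold,
            "out_gain": self.out_gain,
            "convergence_tol": self.convergence_tol,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkParams":
        import yaml

        doc = yaml.safe_load(text)
        return cls(
            layers=tuple(LayerSpec(**l) for l in doc["layers"]),
            projections=tuple(ProjectionSpec(**p) for p in doc["projections"]),
            n_settle_cycles=doc.get("n_settle_cycles", 80),
            phase_schedule=tuple(doc.get("phase_schedule", (60, 20))),
            weight_init=tuple(doc.get("weight_init", (0.25, 0.75))),
            hebb_fraction=doc.get("hebb_fraction", 0.2),
            step_size=doc.get("step_size", 0.5),
            ramp_sharpness=doc.get("ramp_sharpness", 0.3),
            out_threshold=doc.get("out_threshold", 0.3),
            out_gain=doc.get("out_gain", 0.1),
            convergence_tol=doc.get("convergence_tol", 1e-4),
        )


def default_params(tsp_rate: float = 0.3, msp_rate: float = 0.05,
                   ca3_ca1_scale: float = 1.0, ecin_ca1_scale: float = 1.0) -> NetworkParams:
    """Default parameterization.

    Layer sizes and winner counts are an order-of-magnitude match to the
    standard hippocampal-subfield model family: DG much larger and much
    sparser than CA3, CA1 denser than both and in the graded
    low-inhibition regime.  The TSP learning rate is six times the MSP
    rate, so novel high-error items are absorbed quickly by the sparse
    pathway while the dense pathway accumulates regularities slowly.  The
    ``*_scale`` arguments expose the CA3->CA1 and EC_in->CA1 connectivity
    scaling (1.0 = fully connected, the healthy-adult setting); the
    EC_out->CA1 feedback enters with a reduced mixing weight so the
    feedforward cue dominates CA1's code.
    """
    layers = (
        LayerSpec("EC_in", 10, 5),
        LayerSpec("DG", 400, 4),
        LayerSpec("CA3", 80, 6),
        LayerSpec("CA1", 100, 25, soft_inhibition=True),
        LayerSpec("EC_out", 10, 5),
    )
    projections = (
        ProjectionSpec("EC_in", "DG", "TSP", tsp_rate),
        ProjectionSpec("EC_in", "CA3", "TSP", tsp_rate),
        ProjectionSpec("DG", "CA3", "TSP", tsp_rate),
        ProjectionSpec("CA3", "CA1", "TSP", tsp_rate, strength_scale=ca3_ca1_scale),
        ProjectionSpec("EC_in", "CA1", "MSP", msp_rate, strength_scale=ecin_ca1_scale),
        ProjectionSpec("CA1", "EC_out", "output", msp_rate),
        ProjectionSpec("EC_out", "CA1", "MSP", msp_rate, rel_weight=0.3),
        ProjectionSpec("EC_out", "EC_in", "bigloop", 0.0),
    )
    return NetworkParams(layers=layers, projections=projections)


@dataclass
class NetworkState:
    """Weights and most recent settled activations."""

    params: NetworkParams
    weights: dict  # (source, target) -> (n_source, n_target) array in [0, 1]
    activations: dict  # layer -> (n_units,) array in [0, 1]
    trial_count: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            params=self.params,
            weights={k: w.copy() for k, w in self.weights.items()},
            activations={k: a.copy() for k, a in self.activations.items()},
            trial_count=self.trial_count,
        )


@dataclass(frozen=True)
class TestSnapshot:
    """Settled activations of all 10 stimuli at one checkpoint.

    ``activations[layer]`` has shape (10, n_units) with rows in the
    canonical stimulus order.
    """

    checkpoint: int
    activations: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for layer, a in self.activations.items():
            if a.shape[0] != len(CANONICAL_ORDER) or not np.all(np.isfinite(a)):
                raise ValueError(f"bad snapshot for layer {layer}")


def init_network(params: NetworkParams | None = None, seed: int = 0) -> NetworkState:
    """Create a network with uniform random weights (seeded).

    The big-loop projection EC_out -> EC_in is initialized to the identity
    and does not learn: it copies the network's current output guess back
    into any unclamped input units.
    """
    params = params or default_params()
    rng = np.random.default_rng(seed)
    layer = params.layer
    lo, hi = params.weight_init
    weights: dict = {}
    for p in params.projections:
        shape = (layer[p.source].n_units, layer[p.target].n_units)
        if p.pathway == "bigloop":
            weights[(p.source, p.target)] = np.eye(*shape)
        else:
            weights[(p.source, p.target)] = rng.uniform(lo, hi, size=shape)
    activations = {name: np.zeros(layer[name].n_units) for name in LAYERS}
    return NetworkState(params=params, weights=weights, activations=activations)


# ---------------------------------------------------------------------------
# dynamics


def _kwta_ramp(net: np.ndarray, k: int, sharpness: float = 0.3) -> np.ndarray:
    """k-winners-take-all ramp applied per column.

    Units at or below the midpoint between the k-th and (k+1)-th largest
    net input are silenced; the remainder rise linearly and saturate at 1
    once they exceed ``sharpness`` of the layer's above-threshold range,
    so the strongest winners are near-binary while marginal winners stay
    graded.  The transform is invariant to affine rescaling of the net
    input, which keeps the dynamics bounded without tuning gains.
    """
    n = net.shape[0]
    if k >= n:
        theta = net.min(axis=0, keepdims=True) - 1.0
    else:
        part = np.partition(net, n - k - 1, axis=0)
        theta = 0.5 * (part[n - k - 1] + part[n - k])
    top = net.max(axis=0, keepdims=True)
    denom = np.maximum(sharpness * (top - theta), 1e-12)
    return np.clip((net - theta) / denom, 0.0, 1.0)


def _soft_kwta(net: np.ndarray, k: int, temp: float) -> np.ndarray:
    """Graded competition: logistic squash around the k-WTA threshold with
    a temperature proportional to the above-threshold range.  Sub-threshold
    units keep small graded activity, so the layer's code stays distributed
    and correlated with its input drive."""
    n = net.shape[0]
    part = np.partition(net, n - k - 1, axis=0)
    theta = 0.5 * (part[n - k - 1] + part[n - k])
    top = net.max(axis=0, keepdims=True)
    tau = np.maximum(temp * (top - theta), 1e-12)
    return 1.0 / (1.0 + np.exp(-(net - theta) / tau))


def _settle(state: NetworkState, ec_in_value: np.ndarray, ec_in_mask: np.ndarray,
            ec_out_value: np.ndarray | None, n_cycles: int,
            init: Mapping[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
    """Iterate the rate dynamics and return settled activations.

    ``ec_in_value`` is (10,) or (10, m); ``ec_in_mask`` marks which EC_in
    units are clamped.  If ``ec_out_value`` is given, EC_out is clamped to
    it.  Weights are never modified.
    """
    params = state.params
    layer = params.layer
    W = state.weights
    # expected-activity normalization per source layer
    norm = {name: float(layer[name].k_active) for name in LAYERS}
    scale = {(p.source, p.target): p.strength_scale * p.rel_weight
             for p in params.projections}

    cols = ec_in_value.shape[1] if ec_in_value.ndim == 2 else None

    def zeros(name: str) -> np.ndarray:
        n = layer[name].n_units
        return np.zeros((n, cols)) if cols else np.zeros(n)

    a = {name: zeros(name) for name in LAYERS}
    if init is not None:
        for name in LAYERS:
            a[name] = init[name].copy()
    ec_in = a["EC_in"]
    ec_in[ec_in_mask] = ec_in_value[ec_in_mask]
    if ec_out_value is not None:
        a["EC_out"] = ec_out_value.astype(float).copy()

    dt = params.step_size
    free_in = ~ec_in_mask
    any_free_in = bool(np.any(free_in))

    def drive(src: str, tgt: str) -> np.ndarray:
        w = W[(src, tgt)]
        return (w.T @ a[src]) * (scale[(src, tgt)] / norm[src])

    # hot loop: layer updates are unrolled and use ndarray methods to keep
    # per-cycle Python overhead low
    inputs_by_layer = (
        ("DG", (("EC_in", "DG"),)),
        ("CA3", (("EC_in", "CA3"), ("DG", "CA3"))),
        ("CA1", (("CA3", "CA1"), ("EC_in", "CA1"), ("EC_out", "CA1"))),
    )
    soft = {name: layer[name].soft_inhibition for name in HIDDEN_LAYERS}
    k_of = {name: layer[name].k_active for name in HIDDEN_LAYERS}

    for _ in range(n_cycles):
        max_delta = 0.0
        for name, inputs in inputs_by_layer:
            net = drive(*inputs[0])
            for pair in inputs[1:]:
                net += drive(*pair)
            if soft[name]:
                target = _soft_kwta(net, k_of[name], params.soft_temp)
            else:
                target = _kwta_ramp(net, k_of[name], params.ramp_sharpness)
            new = a[name] + dt * (target - a[name])
            max_delta = max(max_delta, float(np.abs(new - a[name]).max()))
            a[name] = new
        if ec_out_value is None:
            net = drive("CA1", "EC_out")
            target = 1.0 / (1.0 + np.exp(-(net - params.out_threshold) / params.out_gain))
            new = a["EC_out"] + dt * (target - a["EC_out"])
            max_delta = max(max_delta, float(np.abs(new - a["EC_out"]).max()))
            a["EC_out"] = new
        if any_free_in:
            # big-loop recurrence: EC_out pattern-completes unclamped input units
            loop = W[("EC_out", "EC_in")].T @ a["EC_out"]
            new = a["EC_in"].copy()
            new[free_in] += dt * (np.clip(loop, 0.0, 1.0)[free_in] - new[free_in])
            max_delta = max(max_delta, float(np.abs(new - a["EC_in"]).max()))
            a["EC_in"] = new
        if not np.isfinite(max_delta):
            raise DynamicsError("activation dynamics diverged (non-finite values)")
        if max_delta < params.convergence_tol:
            break
    for v in a.values():
        if not np.all(np.isfinite(v)):
            raise DynamicsError("activation dynamics diverged (non-finite values)")
    return a


def settle(state: NetworkState, input_pattern: Sequence[float],
           clamp: Sequence[bool] | None = None,
           n_cycles: int | None = None) -> dict[str, np.ndarray]:
    """Settle the network on one input without changing any weight.

    ``clamp`` marks which EC_in units are externally driven (default: all
    ten).  Returns the final per-layer activations.
    """
    pattern = np.asarray(input_pattern, dtype=float)
    if np.any(pattern < 0) or np.any(pattern > 1):
        raise ValueError("input values must lie in [0, 1]")
    mask = np.ones(pattern.shape[0], dtype=bool) if clamp is None else np.asarray(clamp, dtype=bool)
    n = state.params.n_settle_cycles if n_cycles is None else n_cycles
    a = _settle(state, pattern, mask, None, n)
    state.activations = {k: v.copy() for k, v in a.items()}
    return a


# ---------------------------------------------------------------------------
# learning


def train_trial(state: NetworkState, pattern: Sequence[float]) -> NetworkState:
    """One two-phase learning trial on a full 10-unit stimulus encoding.

    Expectation phase: the cue is presented as at test — feature units of
    EC_in clamped, the category unit pair left free so big-loop
    recurrence fills it with the network's own guess — and EC_out settles
    freely.  Outcome phase: EC_in and EC_out are both clamped to the full
    true pattern.  Each learnable projection then moves by

        lr * (outcome coproduct - expectation coproduct)
        + lr * hebb * (soft-bounded Hebbian term on the outcome phase)

    with weights clipped to [0, 1].  Because the expectation phase runs
    on the network's own prediction, early-learning errors re-enter via
    the big loop and are transiently bound into the hidden codes — the
    source of category blurring when irregular items arrive before the
    regularities have crystallized.  The state is updated in place and
    returned.
    """
    params = state.params
    pattern = np.asarray(pattern, dtype=float)
    n_exp, n_out = params.phase_schedule

    cue = pattern.copy()
    cue[8:] = 0.0
    cue_mask = np.zeros(pattern.shape[0], dtype=bool)
    cue_mask[:8] = True
    full_mask = np.ones(pattern.shape[0], dtype=bool)

    minus = _settle(state, cue, cue_mask, None, n_exp)
    plus = _settle(state, pattern, full_mask, pattern, n_out, init=minus)

    # Hebbian plasticity operates throughout the trial, so it binds the
    # duration-weighted activity of both phases — including whatever the
    # big loop re-entered during the expectation phase.  The contrastive
    # term is the phase difference only.
    w_exp = n_exp / (n_exp + n_out)
    blend = {name: w_exp * minus[name] + (1.0 - w_exp) * plus[name] for name in LAYERS}
    for p in params.projections:
        if p.learning_rate == 0.0:
            continue
        key = (p.source, p.target)
        w = state.weights[key]
        dw = np.outer(plus[p.source], plus[p.target]) \
            - np.outer(minus[p.source], minus[p.target])
        a_s, a_t = blend[p.source], blend[p.target]
        if p.target in ("DG", "CA3"):
            # competitive Hebbian into the high-inhibition layers: each
            # active receiver moves its whole weight vector toward the
            # sending pattern, releasing inputs it does not fire for, so
            # winners specialize per stimulus (pattern separation); kept
            # slow so separation accrues over the session rather than
            # instantly absorbing every irregular item
            hebb = params.competitive_hebb_fraction * a_t[None, :] * (a_s[:, None] - w)
        else:
            # associative soft-bound Hebbian into the dense layers: only
            # co-active synapses strengthen, preserving distributed overlap
            hebb = params.hebb_fraction * a_s[:, None] * (a_t[None, :] - w)
        w += p.learning_rate * (dw + hebb)
        np.clip(w, 0.0, 1.0, out=w)
    state.activations = {k: v.copy() for k, v in plus.items()}
    state.trial_count += 1
    return state


def test_items(state: NetworkState, stimulus_set: StimulusSet) -> TestSnapshot:
    """Probe the network with all ten stimuli; no weight changes.

    Each cue presents the four feature dimensions and blanks the category
    unit pair (units 8–9 start at zero and are driven only by big-loop
    recurrence), so EC_out has to complete the category from the learned
    circuit.  Stimuli are settled in parallel as columns.
    """
    cues = stimulus_set.encoding_matrix().T.astype(float)  # (10 units, 10 stimuli)
    cues[8:, :] = 0.0
    mask = np.zeros_like(cues, dtype=bool)
    mask[:8, :] = True
    a = _settle(state, cues, mask, None, state.params.n_settle_cycles)
    acts = {name: a[name].T.copy() for name in ("DG", "CA3", "CA1", "EC_out")}
    return TestSnapshot(checkpoint=state.trial_count, activations=acts)


def train_sequence(state: NetworkState, sequence: TrialSequence, stimulus_set: StimulusSet,
                   checkpoints: Sequence[int] = ()) -> tuple[list[TestSnapshot], NetworkState]:
    """Train trial-by-trial, probing all ten stimuli at each checkpoint.

    Checkpoint tests never update weights.  Returns the snapshots in
    checkpoint order together with the final state.
    """
    checkpoints = sorted(set(checkpoints))
    if any(c < 1 or c > len(sequence) for c in checkpoints):
        raise ValueError("checkpoints must lie within the sequence")
    snapshots: list[TestSnapshot] = []
    pending = list(checkpoints)
    for trial in sequence:
        train_trial(state, stimulus_set[trial.stimulus_id].encoding)
        if pending and state.trial_count == pending[0]:
            snapshots.append(test_items(state, stimulus_set))
            pending.pop(0)
    return snapshots, state


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class BatchEnsemble:
    """Outputs of ``run_batches``: per-batch accuracy records, per-batch
    end-of-learning snapshots, and running ensemble-mean snapshots at
    every checkpoint."""

    condition: str
    checkpoints: tuple[int, ...]
    accuracy: pd.DataFrame
    final_snapshots: Mapping[str, np.ndarray]  # layer -> (n_batches, 10, n_units)
    mean_snapshots: Mapping[int, Mapping[str, np.ndarray]]  # checkpoint -> layer -> (10, n_units)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.accuracy.to_csv(out / "accuracy.csv", index=False)
        manifest = {"condition": self.condition, "checkpoints": list(self.checkpoints),
                    "layers": sorted(self.mean_snapshots[self.checkpoints[0]].keys())}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for cp, layers in self.mean_snapshots.items():
            for layer, mat in layers.items():
                np.savetxt(out / f"mean_{layer}_cp{cp}.txt", mat)


def run_batches(condition: str, n_batches: int, base_seed: int,
                params: NetworkParams | None = None,
                stimulus_set: StimulusSet | None = None,
                checkpoints: Sequence[int] | None = None) -> BatchEnsemble:
    """Run an ensemble of independently initialized simulations.

    Batch ``b`` uses seed ``base_seed + b`` for both weight initialization
    and sequence shuffling.  Accuracy (Luce-choice readout of EC_out's
    category pair) is recorded for every stimulus at every checkpoint;
    full per-batch activation snapshots are kept for the final checkpoint
    only, with ensemble means accumulated at every checkpoint.
    """
    from .readout import snapshot_accuracy

    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    params = params or default_params()
    stimulus_set = stimulus_set or build_type3_structure()
    checkpoints = tuple(checkpoints) if checkpoints is not None else checkpoint_schedule(condition)
    final_cp = checkpoints[-1]

    records = []
    final: dict[str, list[np.ndarray]] = {l: [] for l in ("DG", "CA3", "CA1", "EC_out")}
    sums: dict[int, dict[str, np.ndarray]] = {}
    for b in range(n_batches):
        seed = base_seed + b
        state = init_network(params, seed=seed)
        seq = generate_learning_sequence(stimulus_set, SequenceConfig(condition, seed=seed))
        snapshots, _ = train_sequence(state, seq, stimulus_set, checkpoints)
        for snap in snapshots:
            acc = snapshot_accuracy(snap, stimulus_set)
            for sid, value in acc.items():
                s = stimulus_set[sid]
                records.append((b, condition, sid, s.role, s.category, snap.checkpoint, value))
            layers = sums.setdefault(snap.checkpoint, {})
            for layer, mat in snap.activations.items():
                if layer in layers:
                    layers[layer] += mat
                else:
                    layers[layer] = mat.copy()
            if snap.checkpoint == final_cp:
                for layer, mat in snap.activations.items():
                    final[layer].append(mat)
    accuracy = pd.DataFrame(
        records,
        columns=["batch", "condition", "stimulus_id", "role", "category", "checkpoint", "accuracy"],
    )
    mean_snapshots = {
        cp: {layer: mat / n_batches for layer, mat in layers.items()}
        for cp, layers in sums.items()
    }
    final_snapshots = {layer: np.stack(mats) for layer, mats in final.items()}
    return BatchEnsemble(
        condition=condition,
        checkpoints=checkpoints,
        accuracy=accuracy,
        final_snapshots=final_snapshots,
        mean_snapshots=mean_snapshots,
    )
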