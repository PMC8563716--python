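"""Hippocampal network: initialization, settling dynamics, learning, and
ensemble contracts."""

import numpy as np
import pytest

import hipporpe as hp
from hipporpe.network import (
    PROJECTION_GRAPH,
    LayerSpec,
    NetworkParams,
    ProjectionSpec,
    _settle,
    default_params,
)
from hipporpe.readout import snapshot_accuracy


class TestInit:
    def test_seeded_determinism(self):
        a, b = hp.init_network(seed=1), hp.init_network(seed=1)
        for key in a.weights:
            assert np.array_equal(a.weights[key], b.weights[key])
        c = hp.init_network(seed=2)
        assert any(not np.array_equal(a.weights[k], c.weights[k]) for k in a.weights)

    def test_projection_graph(self):
        params = default_params()
        edges = {(p.source, p.target) for p in params.projections}
        assert edges == {(s, t) for s, t, _ in PROJECTION_GRAPH}
        assert len(edges) == 8

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError, match="TSP"):
            default_params(tsp_rate=0.05, msp_rate=0.1)

    def test_sparsity_ordering_enforced(self):
        params = default_params()
        layers = tuple(
            LayerSpec("DG", 400, 300) if l.name == "DG" else l for l in params.layers)
        with pytest.raises(ValueError, match="DG < CA3 < CA1"):
            NetworkParams(layers=layers, projections=params.projections)

    def test_yaml_round_trip(self):
        params = default_params()
        clone = NetworkParams.from_yaml(params.to_yaml())
        assert clone == params


class TestSettle:
    def test_zero_input_zero_weights(self, stimulus_set):
        state = hp.init_network(seed=0)
        for key in state.weights:
            state.weights[key][:] = 0.0
        acts = hp.settle(state, np.zeros(10))
        for layer in ("EC_out",):
            assert np.all(acts[layer] < 0.05)
        assert np.all(acts["EC_in"] == 0.0)

    def test_active_fraction_ordering(self, rng):
        """Realized active-unit fractions follow the inhibition budgets
        DG <= CA3 <= CA1 on random inputs, and hard k-WTA never exceeds
        its winner count."""
        state = hp.init_network(seed=3)
        for _ in range(100):
            x = rng.integers(0, 2, size=10).astype(float)
            acts = hp.settle(state, x)
            frac = {l: float((acts[l] > 0.5).mean()) for l in ("DG", "CA3", "CA1")}
            assert frac["DG"] <= frac["CA3"] <= frac["CA1"]
            assert int((acts["DG"] > 0.5).sum()) <= 4
            assert int((acts["CA3"] > 0.5).sum()) <= 6
            assert int((acts["CA1"] > 0.5).sum()) <= int(25 * 1.1)

    def test_settle_reaches_fixed_point(self, stimulus_set):
        state = hp.init_network(seed=5)
        x = stimulus_set["PA1"].encoding.astype(float)
        first = hp.settle(state, x)
        second = _settle(state, x, np.ones(10, bool), None,
                         state.params.n_settle_cycles, init=first)
        for layer in ("DG", "CA3", "CA1", "EC_out"):
            assert np.max(np.abs(second[layer] - first[layer])) < 1e-3

    def test_settle_does_not_touch_weights(self, stimulus_set):
        state = hp.init_network(seed=5)
        before = {k: w.copy() for k, w in state.weights.items()}
        hp.settle(state, stimulus_set["EA"].encoding.astype(float))
        for k in before:
            assert np.array_equal(before[k], state.weights[k])

    def test_input_validation(self):
        state = hp.init_network(seed=0)
        with pytest.raises(ValueError):
            hp.settle(state, np.full(10, 2.0))


class TestTrainTrial:
    def test_zero_rate_changes_nothing(self, stimulus_set):
        """With every learning rate at zero a trial leaves all weights
        untouched.  (Built by field surgery because the public
        constructor enforces TSP > MSP on learnable networks.)"""
        base = default_params()
        zero_projs = tuple(
            ProjectionSpec(p.source, p.target, p.pathway, 0.0, p.strength_scale, p.rel_weight)
            for p in base.projections)
        params = object.__new__(NetworkParams)
        for field_name, value in vars(base).items():
            object.__setattr__(params, field_name, value)
        object.__setattr__(params, "projections", zero_projs)
        state = hp.init_network(params, seed=1)
        before = {k: w.copy() for k, w in state.weights.items()}
        hp.train_trial(state, stimulus_set["PA1"].encoding.astype(float))
        for k in before:
            assert np.array_equal(before[k], state.weights[k])
        assert state.trial_count == 1

    def test_single_pattern_memorization(self, stimulus_set):
        """Twenty repetitions of one pattern raise its readout accuracy."""
        state = hp.init_network(seed=7)
        before = snapshot_accuracy(hp.test_items(state, stimulus_set), stimulus_set)["PA1"]
        enc = stimulus_set["PA1"].encoding.astype(float)
        for _ in range(20):
            hp.train_trial(state, enc)
        after = snapshot_accuracy(hp.test_items(state, stimulus_set), stimulus_set)["PA1"]
        assert after > before

    def test_training_determinism(self, stimulus_set):
        seq = hp.generate_learning_sequence(stimulus_set, hp.SequenceConfig("early", seed=2))
        finals = []
        for _ in range(2):
            state = hp.init_network(seed=2)
            for trial in list(seq)[:20]:
                hp.train_trial(state, stimulus_set[trial.stimulus_id].encoding.astype(float))
            finals.append(state)
        for k in finals[0].weights:
            assert np.array_equal(finals[0].weights[k], finals[1].weights[k])

    def test_weights_stay_bounded(self, stimulus_set):
        state = hp.init_network(seed=9)
        seq = hp.generate_learning_sequence(stimulus_set, hp.SequenceConfig("early", seed=9))
        for trial in list(seq)[:60]:
            hp.train_trial(state, stimulus_set[trial.stimulus_id].encoding.astype(float))
        for w in state.weights.values():
            assert w.min() >= 0.0 and w.max() <= 1.0


class TestTrainSequence:
    def test_snapshot_counts(self, stimulus_set):
        seq = hp.generate_learning_sequence(stimulus_set, hp.SequenceConfig("early", seed=1))
        snaps, _ = hp.train_sequence(hp.init_network(seed=1), seq, stimulus_set,
                                     checkpoints=(144,))
        assert len(snaps) == 1 and snaps[0].checkpoint == 144
        assert set(snaps[0].activations) == {"DG", "CA3", "CA1", "EC_out"}
        assert all(a.shape[0] == 10 for a in snaps[0].activations.values())

    def test_schedule_lengths(self, small_ensembles):
        assert len(small_ensembles["early"].checkpoints) == 7
        assert len(small_ensembles["delayed"].checkpoints) == 8

    def test_checkpoint_test_is_read_only(self, stimulus_set):
        state = hp.init_network(seed=4)
        seq = hp.generate_learning_sequence(stimulus_set, hp.SequenceConfig("early", seed=4))
        for trial in list(seq)[:12]:
            hp.train_trial(state, stimulus_set[trial.stimulus_id].encoding.astype(float))
        before = {k: w.copy() for k, w in state.weights.items()}
        snap1 = hp.test_items(state, stimulus_set)
        snap2 = hp.test_items(state, stimulus_set)
        for k in before:
            assert np.array_equal(before[k], state.weights[k])
        for layer in snap1.activations:
            assert np.array_equal(snap1.activations[layer], snap2.activations[layer])


class TestEnsembles:
    def test_untrained_accuracy_near_chance(self, stimulus_set):
        """With random weights the category readout carries no
        information: mean accuracy over 50 seeds sits at 0.5 +- 0.1."""
        means = []
        for seed in range(50):
            snap = hp.test_items(hp.init_network(seed=seed), stimulus_set)
            means.append(np.mean(list(snapshot_accuracy(snap, stimulus_set).values())))
        assert abs(float(np.mean(means)) - 0.5) < 0.1

    def test_ensemble_shapes_and_roles(self, small_ensembles):
        e = small_ensembles["early"]
        assert e.final_snapshots["CA1"].shape == (12, 10, 100)
        acc = e.accuracy
        assert set(acc.columns) >= {"batch", "condition", "stimulus_id", "role",
                                    "category", "checkpoint", "accuracy"}
        assert acc["accuracy"].between(0, 1).all()
        # per checkpoint, every batch contributes all 10 stimuli
        counts = acc.groupby(["batch", "checkpoint"]).size()
        assert (counts == 10).all()

    def test_conditions_share_role_totals_with_distinct_sequences(self, stimulus_set):
        early = hp.generate_learning_sequence(stimulus_set, hp.SequenceConfig("early", seed=1))
        delayed = hp.generate_learning_sequence(stimulus_set, hp.SequenceConfig("delayed", seed=1))
        assert early.stimulus_ids() != delayed.stimulus_ids()
        roles = lambda s: sorted(stimulus_set[t.stimulus_id].role for t in s)
        assert roles(early) == roles(delayed)

    def test_autoencoding_memorization_contract(self, small_ensembles, stimulus_set):
        """After 144 trials the settled EC_out reproduces prototype
        feature units with cosine > 0.85 (median across batches): the
        package's memorization contract for the dense pathway."""
        coss = []
        for seed in (910_000 + b for b in range(12)):
            state = hp.init_network(seed=seed)
            seq = hp.generate_learning_sequence(
                stimulus_set, hp.SequenceConfig("early", seed=seed))
            hp.train_sequence(state, seq, stimulus_set)
            for sid in ("PA1", "PA2", "PB1", "PB2"):
                enc = stimulus_set[sid].encoding.astype(float)
                acts = _settle(state, enc, np.ones(10, bool), None, 80)
                u, v = acts["EC_out"][:8], enc[:8]
                coss.append(float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v))))
        assert float(np.median(coss)) > 0.85

    def test_sparsity_ordering_in_snapshots(self, small_ensembles):
        for ens in small_ensembles.values():
            frac = {l: float((ens.final_snapshots[l] > 0.5).mean())
                    for l in ("DG", "CA3", "CA1")}
            assert frac["DG"] < frac["CA3"] < frac["CA1"]

    def test_save_round_trip(self, small_ensembles, tmp_path):
        ens = small_ensembles["early"]
        ens.save(tmp_path / "runs")
        import json
        manifest = json.loads((tmp_path / "runs" / "manifest.json").read_text())
        assert manifest["condition"] == "early"
        mat = np.loadtxt(tmp_path / "runs" / "mean_CA1_cp144.txt")
        assert np.allclose(mat, ens.mean_snapshots[144]["CA1"])
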