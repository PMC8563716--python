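"""Sammon mapping, Procrustes alignment, and trajectory assembly."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform

import hipporpe as hp
from hipporpe.embedding import (
    Configuration2D,
    DissimilarityMatrix,
    procrustes_align,
    sammon_map,
    sammon_stress,
    to_dissimilarity,
    trajectory,
)
from hipporpe.rsa import rsa_matrix


def dmat(points):
    return DissimilarityMatrix(values=squareform(pdist(points)))


class TestToDissimilarity:
    def test_affine_map(self, rng):
        m = rsa_matrix(rng.normal(size=(10, 30)))
        d = to_dissimilarity(m)
        assert np.all(np.diag(d.values) == 0)
        off = ~np.eye(10, dtype=bool)
        assert np.allclose(d.values[off], 1.0 - m.values[off], atol=1e-12)
        # r = 1 -> d = 0 and r = -1 -> d = 2 are endpoints of the affine map
        assert np.all(d.values >= 0) and np.all(d.values <= 2.0 + 1e-12)


class TestSammon:
    def test_planar_square_is_exact(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        cfg = sammon_map(dmat(square))
        assert cfg.stress < 1e-6

    def test_equilateral_triangle_is_exact(self):
        d = DissimilarityMatrix(values=np.ones((3, 3)) - np.eye(3))
        assert sammon_map(d).stress < 1e-6

    def test_planar_inputs_exact_for_many_seeds(self, rng):
        pts = rng.uniform(size=(6, 2))
        d = dmat(pts)
        for seed in range(10):
            assert sammon_map(d, seed=seed).stress < 1e-6

    def test_tetrahedron_matches_brute_force(self):
        """The regular tetrahedron cannot be flattened; the reached
        stress must match a dense multi-restart direct optimizer."""
        delta = np.ones((4, 4)) - np.eye(4)
        cfg = sammon_map(DissimilarityMatrix(values=delta))

        def objective(flat):
            return sammon_stress(delta, flat.reshape(4, 2))

        rng = np.random.default_rng(0)
        best = np.inf
        for _ in range(40):
            res = minimize(objective, rng.normal(size=8), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, res.fun)
        assert cfg.stress == pytest.approx(best, abs=1e-3)

    def test_stress_invariant_to_similarity_transform(self, rng):
        pts = rng.uniform(size=(5, 2))
        d = dmat(rng.uniform(size=(5, 2)))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        s0 = sammon_stress(d.values, pts)
        assert sammon_stress(d.values, pts @ rot + 3.0) == pytest.approx(s0, abs=1e-12)

    def test_zero_offdiagonal_policy(self):
        delta = np.ones((4, 4)) - np.eye(4)
        delta[0, 1] = delta[1, 0] = 0.0
        with pytest.raises(ValueError):
            sammon_map(DissimilarityMatrix(values=delta))
        cfg = sammon_map(DissimilarityMatrix(values=delta), jitter="epsilon")
        assert np.isfinite(cfg.stress)

    def test_deterministic_under_seed(self, rng):
        d = dmat(rng.uniform(size=(7, 3)))
        a, b = sammon_map(d, seed=3), sammon_map(d, seed=3)
        assert np.array_equal(a.points, b.points)


class TestProcrustes:
    def test_recovers_similarity_copies(self, rng):
        ref = Configuration2D(points=rng.uniform(size=(10, 2)), stress=0.0)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        refl = np.array([[1.0, 0.0], [0.0, -1.0]])
        for transform in (rot, rot @ refl):
            moved = Configuration2D(points=2.5 * ref.points @ transform + [3, -1], stress=0.0)
            aligned, disparity = procrustes_align(moved, ref)
            assert disparity < 1e-10
            assert np.allclose(aligned.points, ref.points, atol=1e-6)

    def test_disparity_matches_scipy_closed_form(self, rng):
        """Independent SVD-based implementation (scipy.spatial.procrustes)
        gives the same normalized residual."""
        x = rng.normal(size=(10, 2))
        y = rng.normal(size=(10, 2))
        _, disparity = procrustes_align(
            Configuration2D(points=y, stress=0.0), Configuration2D(points=x, stress=0.0))
        _, _, scipy_disp = scipy_procrustes(x, y)
        # scipy normalizes both configurations; its disparity equals ours
        # up to the reference's centered sum of squares (scipy sets it to 1)
        assert disparity == pytest.approx(scipy_disp * 1.0, rel=1e-8)

    def test_alignment_preserves_stress(self, rng):
        d = dmat(rng.uniform(size=(6, 3)))
        cfg = sammon_map(d)
        ref = Configuration2D(points=rng.uniform(size=(6, 2)), stress=0.0)
        aligned, _ = procrustes_align(cfg, ref)
        assert aligned.stress == cfg.stress

    def test_degenerate_reference_rejected(self):
        flat = Configuration2D(points=np.zeros((4, 2)) + 1.0, stress=0.0)
        ok = Configuration2D(points=np.arange(8, dtype=float).reshape(4, 2), stress=0.0)
        with pytest.raises(ValueError):
            procrustes_align(ok, flat)


class TestTrajectory:
    def _matrices(self, rng, checkpoints):
        return {cp: rsa_matrix(rng.normal(size=(10, 40))) for cp in checkpoints}

    def test_series_lengths_match_schedules(self, rng):
        for condition, expect in (("early", 7), ("delayed", 8)):
            cps = hp.checkpoint_schedule(condition)
            series = trajectory(self._matrices(rng, cps), cps)
            assert len(series) == expect
            assert [c.checkpoint for c in series] == list(cps)

    def test_final_checkpoint_self_aligns(self, rng):
        cps = hp.checkpoint_schedule("early")
        mats = self._matrices(rng, cps)
        series = trajectory(mats, cps)
        solo = sammon_map(to_dissimilarity(mats[144]), jitter="epsilon")
        _, disparity = procrustes_align(series[-1], solo)
        assert disparity < 1e-10

    def test_missing_checkpoint_is_explicit(self, rng):
        cps = hp.checkpoint_schedule("early")
        mats = self._matrices(rng, cps[:-1])
        with pytest.raises(KeyError):
            trajectory(mats, cps)
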