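"""Assembly detection, quadratic activity and modulation testing."""

import warnings

import numpy as np
import pytest

from cahub import (
    AssemblySpec,
    InVivoSimSpec,
    compute_assembly_activity,
    detect_assemblies,
    gen_invivo_session,
    test_assembly_modulation,
)
from cahub.assemblies import compute_assembly_activity_kept

warnings.filterwarnings("ignore", message=".*did not converge.*")


def planted_session(seed, n_cells=60, n_assemblies=2, size=12,
                    duration_s=900.0):
    members = [
        tuple(range(k * size, (k + 1) * size)) for k in range(n_assemblies)
    ]
    asm = tuple(
        AssemblySpec(members=m, rate_hz=0.05, member_prob=0.9) for m in members
    )
    spec = InVivoSimSpec(
        seed=seed, n_cells=n_cells, duration_s=duration_s, assemblies=asm,
        sce_rate_hz=0.0, loco_modulated_fraction=0.0,
    )
    r, eps, gt = gen_invivo_session(spec)
    truth = np.zeros((n_assemblies, n_cells))
    for k, m in enumerate(members):
        truth[k, list(m)] = 1
    truth /= np.linalg.norm(truth, axis=1, keepdims=True)
    return r, eps, truth


class TestActivityQuadraticForm:
    def test_zero_vector_gives_zero(self):
        w = np.array([[0.6, 0.8, 0.0]])
        assert compute_assembly_activity_kept(w, np.zeros((3, 4))).max() == 0.0

    def test_unit_pattern_identity(self):
        # z = w_k  ->  R_k = 1 - sum_i w_i^4 (diagonal removed)
        g = np.random.default_rng(2)
        w = g.normal(size=8)
        w /= np.linalg.norm(w)
        R = compute_assembly_activity_kept(w[None, :], w[:, None])
        assert R[0, 0] == pytest.approx(1.0 - np.sum(w**4))

    def test_matches_explicit_projection_matrix(self):
        g = np.random.default_rng(3)
        w = g.normal(size=10)
        w /= np.linalg.norm(w)
        z = g.normal(size=(10, 25))
        P = np.outer(w, w)
        np.fill_diagonal(P, 0.0)
        expect = np.einsum("ti,ij,tj->t", z.T, P, z.T)
        got = compute_assembly_activity_kept(w[None, :], z)[0]
        assert np.allclose(got, expect, atol=1e-10)

    def test_sign_flip_invariance(self):
        g = np.random.default_rng(4)
        w = g.normal(size=(2, 7))
        z = g.normal(size=(7, 30))
        assert np.allclose(
            compute_assembly_activity_kept(w, z),
            compute_assembly_activity_kept(-w, z),
        )

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            compute_assembly_activity_kept(np.ones((1, 3)), np.ones((4, 5)))


class TestDetectAssemblies:
    def test_planted_patterns_recovered(self):
        r, eps, truth = planted_session(seed=0)
        aset = detect_assemblies(r, eps.rest, n_shuffles=150, rng=1)
        assert aset.n_significant == len(truth)
        cos = np.abs(truth @ aset.patterns.T).max(axis=1)
        assert np.all(cos > 0.8)

    def test_independent_raster_yields_no_patterns(self):
        spec = InVivoSimSpec(seed=60, n_cells=60, duration_s=900.0,
                             sce_rate_hz=0.0, loco_modulated_fraction=0.0)
        r, eps, _ = gen_invivo_session(spec)
        aset = detect_assemblies(r, eps.rest, n_shuffles=150, rng=2)
        assert aset.n_significant == 0

    def test_count_bounded_by_cells_and_bins(self):
        r, eps, _ = planted_session(seed=1)
        aset = detect_assemblies(r, eps.rest, n_shuffles=100, rng=3)
        assert aset.n_significant <= min(r.n_cells, aset.zcounts.shape[1])

    def test_permuting_cells_permutes_weights(self):
        # detection on a cell-permuted raster recovers the permuted patterns
        r, eps, truth = planted_session(seed=2)
        perm = np.random.default_rng(5).permutation(r.n_cells)
        from cahub import ActivityRaster
        rp = ActivityRaster(r.onsets[perm], r.frame_rate_hz)
        a0 = detect_assemblies(r, eps.rest, n_shuffles=150, rng=6)
        a1 = detect_assemblies(rp, eps.rest, n_shuffles=150, rng=6)
        assert a0.n_significant == a1.n_significant == len(truth)
        cos = np.abs(truth[:, perm] @ a1.patterns.T).max(axis=1)
        assert np.all(cos > 0.8)

    def test_patterns_unit_norm_and_sign_aligned(self):
        r, eps, _ = planted_session(seed=3)
        aset = detect_assemblies(r, eps.rest, n_shuffles=100, rng=7)
        norms = np.linalg.norm(aset.patterns, axis=1)
        assert np.allclose(norms, 1.0)
        for w in aset.patterns:
            assert w[np.argmax(np.abs(w))] > 0

    def test_seed_determinism(self):
        r, eps, _ = planted_session(seed=4)
        a = detect_assemblies(r, eps.rest, n_shuffles=80, rng=11)
        b = detect_assemblies(r, eps.rest, n_shuffles=80, rng=11)
        assert np.array_equal(a.patterns, b.patterns)
        assert np.array_equal(a.activities, b.activities)


class TestAssemblyModulation:
    def test_member_cells_modulated_nonmembers_rare(self):
        r, eps, truth = planted_session(seed=5)
        aset = detect_assemblies(r, eps.rest, n_shuffles=150, rng=8)
        mod = test_assembly_modulation(r, aset, eps.rest, rng=9)
        members = np.flatnonzero(truth.sum(axis=0) > 0)
        others = np.flatnonzero(truth.sum(axis=0) == 0)
        assert mod.significant[members].mean() > 0.9
        assert mod.significant[others].mean() < 0.25

    def test_no_assemblies_not_assessable(self):
        spec = InVivoSimSpec(seed=61, n_cells=40, duration_s=600.0,
                             sce_rate_hz=0.0, loco_modulated_fraction=0.0)
        r, eps, _ = gen_invivo_session(spec)
        aset = detect_assemblies(r, eps.rest, n_shuffles=100, rng=12)
        assert aset.n_significant == 0
        mod = test_assembly_modulation(r, aset, eps.rest, rng=13)
        assert not mod.assessable
        assert not mod.significant.any()

    def test_activity_recomputation_matches_stored(self):
        r, eps, _ = planted_session(seed=6)
        aset = detect_assemblies(r, eps.rest, n_shuffles=100, rng=14)
        assert np.allclose(compute_assembly_activity(aset), aset.activities)
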