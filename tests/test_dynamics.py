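"""Superposition, RMSF, normalized dRMSF, DCCM, and region extraction."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from epistab.datatypes import TrajectoryEnsemble
from epistab.dynamics import (
    DCCMatrix,
    RMSFProfile,
    average_chains,
    compute_dccm,
    compute_rmsf,
    correlated_regions,
    delta_rmsf_norm,
    site_window_mean,
    superpose,
)
from epistab.errors import ValidationError
from epistab.synth import gen_trajectory


def make_ensemble(frames, **kw):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    kw.setdefault("resids", np.arange(1, n + 1))
    kw.setdefault("chains", np.array(["A"] * n))
    return TrajectoryEnsemble(replicates=[frames], **kw)


def brute_force_dccm(frames):
    """Double-loop covariance oracle for small instances."""
    mean = frames.mean(axis=0)
    n = frames.shape[1]
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den_i = den_j = 0.0
            for f in range(frames.shape[0]):
                di = frames[f, i] - mean[i]
                dj = frames[f, j] - mean[j]
                num += float(di @ dj)
                den_i += float(di @ di)
                den_j += float(dj @ dj)
            c[i, j] = num / math.sqrt(den_i * den_j)
    return c


class TestSuperpose:
    def test_pure_rigid_motion_removed(self, rng):
        base = rng.normal(0, 5, (10, 3))
        frames = []
        for k in range(6):
            rot = Rotation.random(random_state=np.random.RandomState(k))
            frames.append(rot.apply(base) + rng.normal(0, 20, 3))
        ens = superpose(make_ensemble(np.stack(frames)))
        prof = compute_rmsf(ens)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_idempotent_on_aligned_trajectory(self, rng):
        base = rng.normal(0, 5, (8, 3))
        frames = np.stack([base + rng.normal(0, 0.01, base.shape) for _ in range(5)])
        once = superpose(make_ensemble(frames))
        twice = superpose(once)
        np.testing.assert_allclose(once.replicates[0], twice.replicates[0], atol=1e-9)

    def test_translation_only_trajectory_centered(self, rng):
        base = rng.normal(0, 5, (6, 3))
        frames = np.stack([base + np.array([dx, 0.0, 0.0]) for dx in range(5)])
        prof = compute_rmsf(superpose(make_ensemble(frames)))
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_iterative_mean_reference_also_removes_rigid_motion(self, rng):
        base = rng.normal(0, 5, (10, 3))
        frames = []
        for k in range(6):
            rot = Rotation.random(random_state=np.random.RandomState(k))
            frames.append(rot.apply(base) + rng.normal(0, 20, 3))
        ens = superpose(make_ensemble(np.stack(frames)), iterative_mean=True)
        np.testing.assert_allclose(compute_rmsf(ens).rmsf, 0.0, atol=1e-9)

    def test_degenerate_geometry_rejected(self):
        line = np.stack([np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])] * 3)
        with pytest.raises(ValidationError):
            superpose(make_ensemble(line))


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        frames = np.tile(np.arange(12.0).reshape(1, 4, 3), (5, 1, 1))
        np.testing.assert_allclose(compute_rmsf(make_ensemble(frames)).rmsf, 0.0)

    def test_alternating_atom_has_unit_rmsf(self):
        # one atom hopping between (0,0,0) and (2,0,0): deviations +-1
        frames = np.zeros((4, 1, 3))
        frames[1::2, 0, 0] = 2.0
        assert compute_rmsf(make_ensemble(frames)).rmsf[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_converges_to_sqrt3(self):
        ens, truth = gen_trajectory(np.zeros((120, 3)), sigmas=1.0, n_frames=10_000, seed=7)
        prof = compute_rmsf(ens)
        np.testing.assert_allclose(prof.rmsf, math.sqrt(3.0), rtol=0.05)
        assert prof.rmsf.mean() == pytest.approx(math.sqrt(3.0), rel=0.01)

    def test_replicates_are_averaged(self, rng):
        frames = rng.normal(0, 1, (50, 5, 3))
        ens2 = TrajectoryEnsemble(replicates=[frames, frames.copy()],
                                  resids=np.arange(1, 6), chains=np.array(["A"] * 5))
        one = compute_rmsf(make_ensemble(frames))
        two = compute_rmsf(ens2)
        np.testing.assert_allclose(one.rmsf, two.rmsf)
        assert two.replicate_averaged


class TestDeltaRMSF:
    def test_identical_profiles_give_zero(self, rng):
        prof = RMSFProfile(np.arange(1, 11), rng.uniform(0.5, 2.0, 10))
        np.testing.assert_allclose(delta_rmsf_norm(prof, prof), 0.0, atol=1e-15)

    def test_invariant_to_uniform_scaling(self, rng):
        r = np.arange(1, 11)
        wt = RMSFProfile(r, rng.uniform(0.5, 2.0, 10))
        var = RMSFProfile(r, rng.uniform(0.5, 2.0, 10))
        d1 = delta_rmsf_norm(var, wt)
        d2 = delta_rmsf_norm(RMSFProfile(r, 2.0 * var.rmsf), RMSFProfile(r, 0.3 * wt.rmsf))
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_single_hotspot_hand_computed(self):
        n, k = 100, 41
        wt = RMSFProfile(np.arange(1, n + 1), np.ones(n))
        var_vals = np.ones(n)
        var_vals[k] = 2.0
        var = RMSFProfile(np.arange(1, n + 1), var_vals)
        d = delta_rmsf_norm(var, wt)
        mean_var = (n - 1 + 2.0) / n  # 1.01
        assert d[k] == pytest.approx(2.0 / mean_var - 1.0)
        off = np.delete(d, k)
        np.testing.assert_allclose(off, 1.0 / mean_var - 1.0)
        assert np.all(off < 0) and d[k] > 0

    def test_zscore_method_is_shift_and_scale_invariant(self, rng):
        r = np.arange(1, 21)
        wt = RMSFProfile(r, rng.uniform(0.5, 2.0, 20))
        var = RMSFProfile(r, rng.uniform(0.5, 2.0, 20))
        d1 = delta_rmsf_norm(var, wt, method="zscore")
        d2 = delta_rmsf_norm(RMSFProfile(r, 3.0 * var.rmsf), wt, method="zscore")
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_residue_mismatch_rejected(self):
        a = RMSFProfile(np.arange(1, 6), np.ones(5))
        b = RMSFProfile(np.arange(2, 7), np.ones(5))
        with pytest.raises(ValidationError):
            delta_rmsf_norm(a, b)


class TestSiteWindowMean:
    def test_constant_profile(self):
        r = np.arange(1, 601)
        assert site_window_mean(r, np.full(600, 3.7), 192, 11) == pytest.approx(3.7)

    def test_linear_profile_symmetric_window(self):
        r = np.arange(1, 601)
        assert site_window_mean(r, r.astype(float), 192, 11) == pytest.approx(192.0)

    def test_window_clipped_at_terminus(self):
        r = np.arange(1, 501)
        # site 3, width 11 -> residues 1..8 -> mean 4.5
        assert site_window_mean(r, r.astype(float), 3, 11) == pytest.approx(4.5)

    def test_even_width_rejected(self):
        with pytest.raises(ValidationError):
            site_window_mean(np.arange(1, 11), np.ones(10), 5, 4)

    def test_site_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            site_window_mean(np.arange(1, 11), np.ones(10), 42, 11)


class TestDCCM:
    def test_matches_brute_force_oracle_on_small_instances(self, rng):
        for n_atoms, n_frames in [(3, 12), (5, 20)]:
            frames = rng.normal(0, 1, (n_frames, n_atoms, 3))
            ens = make_ensemble(frames)
            fast = compute_dccm(ens, min_frames=10).matrix
            slow = brute_force_dccm(frames)
            np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_unit_diagonal_and_symmetry(self, rng):
        frames = rng.normal(0, 1, (30, 6, 3))
        m = compute_dccm(make_ensemble(frames)).matrix
        np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-12)
        np.testing.assert_allclose(m, m.T, atol=1e-15)

    def test_in_phase_and_antiphase_limits(self, rng):
        disp = rng.normal(0, 1, (40, 1, 3))
        frames = np.concatenate([disp, disp, -disp], axis=1)
        m = compute_dccm(make_ensemble(frames)).matrix
        assert m[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert m[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_atom_zeroed_with_warning_record(self, rng):
        frames = rng.normal(0, 1, (20, 3, 3))
        frames[:, 1, :] = 5.0  # frozen atom
        d = compute_dccm(make_ensemble(frames))
        assert d.provenance["zero_variance_atoms"] == [1]
        assert d.matrix[1, 1] == 1.0
        np.testing.assert_allclose(np.delete(d.matrix[1], 1), 0.0)

    def test_planted_block_correlation_recovered(self):
        n = 120
        blocks = [(np.arange(10, 41), np.arange(80, 111), 0.5)]
        ens, truth = gen_trajectory(np.zeros((n, 3)), sigmas=1.0, blocks=blocks,
                                    n_frames=5000, seed=11)
        m = compute_dccm(ens).matrix
        est = m[np.ix_(np.arange(10, 41), np.arange(80, 111))].mean()
        assert est == pytest.approx(0.5, abs=0.03)

    def test_invariant_to_rigid_motion_after_superposition(self, rng):
        base = rng.normal(0, 5, (30, 3))
        ens, _ = gen_trajectory(base, sigmas=0.5, n_frames=60, seed=3)
        plain = compute_dccm(superpose(ens)).matrix
        rot = Rotation.random(random_state=np.random.RandomState(1))
        moved = [np.stack([rot.apply(f) + 7.0 for f in rep]) for rep in ens.replicates]
        ens_moved = TrajectoryEnsemble(replicates=moved, resids=ens.resids, chains=ens.chains)
        m2 = compute_dccm(superpose(ens_moved)).matrix
        np.testing.assert_allclose(plain, m2, atol=1e-9)

    def test_invariant_to_uniform_scaling(self, rng):
        frames = rng.normal(0, 1, (25, 5, 3))
        m1 = compute_dccm(make_ensemble(frames)).matrix
        m2 = compute_dccm(make_ensemble(frames * 4.2)).matrix
        np.testing.assert_allclose(m1, m2, atol=1e-12)


class TestChainAveraging:
    def make_dimer_dccm(self, block_a, block_b, n=4):
        m = np.zeros((2 * n, 2 * n))
        m[:n, :n] = block_a
        m[n:, n:] = block_b
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2
        resids = np.concatenate([np.arange(1, n + 1)] * 2)
        return DCCMatrix(m, resids), np.array(["A"] * n + ["B"] * n)

    def test_identical_chains_unchanged(self, rng):
        a = rng.uniform(-0.5, 0.5, (4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        dccm, chains = self.make_dimer_dccm(a, a)
        out = average_chains(dccm, chains)
        np.testing.assert_allclose(out.matrix, a, atol=1e-12)

    def test_blocks_averaged_arithmetically(self):
        a = np.full((4, 4), 0.4)
        b = np.full((4, 4), 0.6)
        dccm, chains = self.make_dimer_dccm(a, b)
        out = average_chains(dccm, chains)
        off = out.matrix[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)
        np.testing.assert_allclose(np.diag(out.matrix), 1.0)

    def test_monomer_input_is_identity_operation(self, rng):
        a = rng.uniform(-0.3, 0.3, (5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        dccm = DCCMatrix(a, np.arange(1, 6))
        out = average_chains(dccm, np.array(["A"] * 5))
        np.testing.assert_allclose(out.matrix, a)

    def test_broken_pairing_rejected(self):
        dccm, chains = self.make_dimer_dccm(np.eye(4) * 0, np.eye(4) * 0)
        with pytest.raises(ValidationError):
            average_chains(dccm, chains, pairing={1: 1, 2: 2, 3: 3, 4: 99})


class TestCorrelatedRegions:
    def planted(self, value):
        n = 100
        m = np.eye(n)
        m[10:25, 60:80] = value
        m[60:80, 10:25] = value
        return DCCMatrix(m, np.arange(1, n + 1))

    def test_planted_block_recovered(self):
        regions = correlated_regions(self.planted(0.5), threshold=0.2, min_separation=20)
        assert len(regions) == 1
        r = regions[0]
        assert r.resid_range_i == (11, 25)
        assert r.resid_range_j == (61, 80)
        assert r.mean_c == pytest.approx(0.5)
        assert r.kind == "correlated"

    def test_identity_matrix_has_no_regions(self):
        d = DCCMatrix(np.eye(50), np.arange(1, 51))
        assert correlated_regions(d) == []

    def test_negative_block_labelled_anticorrelated(self):
        regions = correlated_regions(self.planted(-0.5))
        assert len(regions) == 1
        assert regions[0].kind == "anticorrelated"
        assert regions[0].mean_c == pytest.approx(-0.5)
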