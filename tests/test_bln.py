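"""BLN potential: energies, forces, minimization, MD, annealing."""

import numpy as np
import pytest

from gdsfold.bln import (BeadSequence, BLNParameters, Conformation, MDConfig,
                         EnergyDivergenceError, anneal_to_minimum,
                         bln_energy, bln_gradient, make_bln_callables,
                         minimize_geometry, run_md_nvt)
from gdsfold.fixtures import extended_chain


def _oracle_energy(coords, seq, params):
    """Straightforward per-term loop, independent of the compiled kernel."""
    n = len(coords)
    s1t, s2t, dih = params.compile_tables(seq)
    e = 0.0
    for i in range(n - 1):
        r = np.linalg.norm(coords[i + 1] - coords[i])
        e += params.k_b * (r - params.sigma) ** 2
    for j in range(1, n - 1):
        u = coords[j - 1] - coords[j]
        v = coords[j + 1] - coords[j]
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        theta = np.arccos(np.clip(cos, -1, 1))
        e += 0.5 * params.k_theta * (theta - params.theta0) ** 2
    for d in range(n - 3):
        b1, b2, b3 = (coords[d + 1] - coords[d], coords[d + 2] - coords[d + 1],
                      coords[d + 3] - coords[d + 2])
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        phi = np.arctan2(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)),
                         np.dot(n1, n2))
        a, b, c = dih[d]
        e += a * (1 + np.cos(phi)) + b * (1 + np.cos(3 * phi)) \
            + c * (1 + np.sin(phi))
    for i in range(n):
        for j in range(i + 3, n):
            r = np.linalg.norm(coords[i] - coords[j])
            sr6 = (params.sigma / r) ** 6
            e += 4 * params.epsilon * s1t[i, j] * (sr6 ** 2 - s2t[i, j] * sr6)
    return e


class TestBeadSequence:
    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            BeadSequence("BLX", "")
        with pytest.raises(ValueError):
            BeadSequence("BLNB", "Q")

    def test_dihedral_length_must_be_n_minus_3(self):
        with pytest.raises(ValueError):
            BeadSequence("BLNB", "HH")
        assert BeadSequence("BLN", "").n_beads == 3


class TestEnergy:
    def test_bonded_dimer_at_equilibrium_is_zero(self):
        seq = BeadSequence("BB", "")
        conf = Conformation([[0, 0, 0], [3.8, 0, 0]])
        assert bln_energy(conf, seq) == pytest.approx(0.0, abs=1e-12)

    def test_equilibrium_triplet_is_zero(self):
        seq = BeadSequence("BLN", "")
        theta0 = 1.8326
        conf = Conformation([
            [3.8 * np.cos(theta0), 3.8 * np.sin(theta0), 0.0],
            [0.0, 0.0, 0.0],
            [3.8, 0.0, 0.0]])
        assert bln_energy(conf, seq) == pytest.approx(0.0, abs=1e-10)

    def test_matches_per_term_oracle(self, small_sequence,
                                     random_conformation):
        params = BLNParameters()
        e = bln_energy(random_conformation, small_sequence, params)
        ref = _oracle_energy(random_conformation.coords, small_sequence,
                             params)
        assert e == pytest.approx(ref, rel=1e-10)

    def test_coincident_nonbonded_beads_signal_singularity(self):
        seq = BeadSequence("BBBB", "H")
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 0, 0]],
                          dtype=float)
        assert not np.isfinite(bln_energy(Conformation(coords), seq))

    def test_rigid_motion_invariance(self, small_sequence,
                                     random_conformation, rng):
        from scipy.spatial.transform import Rotation
        e0 = bln_energy(random_conformation, small_sequence)
        rot = Rotation.random(random_state=np.random.RandomState(0))
        moved = random_conformation.coords @ rot.as_matrix().T \
            + np.array([5.0, -3.0, 11.0])
        assert bln_energy(Conformation(moved), small_sequence) == \
            pytest.approx(e0, abs=1e-9)


class TestGradient:
    def test_dimer_equilibrium_force_is_zero(self):
        seq = BeadSequence("BB", "")
        conf = Conformation([[0, 0, 0], [3.8, 0, 0]])
        assert np.allclose(bln_gradient(conf, seq), 0.0, atol=1e-12)

    def test_matches_central_finite_differences(self, small_sequence,
                                                random_conformation):
        forces = bln_gradient(random_conformation, small_sequence)
        h = 1e-6
        coords = random_conformation.coords
        for i in range(coords.shape[0]):
            for c in range(3):
                cp, cm = coords.copy(), coords.copy()
                cp[i, c] += h
                cm[i, c] -= h
                fd = -(bln_energy(Conformation(cp), small_sequence)
                       - bln_energy(Conformation(cm), small_sequence)) / (2 * h)
                assert forces[i, c] == pytest.approx(fd, abs=1e-5)

    def test_total_force_vanishes_under_translation(self, small_sequence,
                                                    random_conformation):
        forces = bln_gradient(random_conformation, small_sequence)
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-10)


class TestMinimize:
    def test_fixed_point_at_local_minimum(self):
        seq = BeadSequence("BB", "")
        conf = Conformation([[0, 0, 0], [3.8, 0, 0]])
        efn, ffn = make_bln_callables(seq)
        out, e, conv = minimize_geometry(conf, efn, ffn)
        assert conv and e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out.coords, conf.coords, atol=1e-6)

    def test_stretched_dimer_relaxes_to_sigma(self):
        seq = BeadSequence("LL", "")
        conf = Conformation([[0, 0, 0], [5.0, 0, 0]])
        efn, ffn = make_bln_callables(seq)
        out, e, conv = minimize_geometry(conf, efn, ffn)
        assert conv
        assert np.linalg.norm(out.coords[1] - out.coords[0]) == \
            pytest.approx(3.8, abs=1e-6)

    def test_perturbed_minimum_recovers_energy(self, small_sequence):
        efn, ffn = make_bln_callables(small_sequence)
        minimum, e0 = anneal_to_minimum(extended_chain(10), small_sequence,
                                        seed=2)
        noisy = Conformation(minimum.coords + np.random.default_rng(5)
                             .normal(scale=0.1, size=(10, 3)))
        out, e, _ = minimize_geometry(noisy, efn, ffn)
        assert e <= e0 + 1e-6

    def test_energy_never_increases(self, small_sequence,
                                    random_conformation):
        efn, ffn = make_bln_callables(small_sequence)
        e_start = efn(random_conformation.coords)
        _, e, _ = minimize_geometry(random_conformation, efn, ffn)
        assert e <= e_start


class TestMD:
    def test_nve_energy_conservation(self, small_sequence):
        minimum, _ = anneal_to_minimum(extended_chain(10), small_sequence,
                                       seed=2)
        md = MDConfig(dt=1e-3, temperature=0.2, collision_rate=0.0,
                      duration=1.0, seed=3, sample_every=100)
        efn, _ = make_bln_callables(small_sequence)
        traj = run_md_nvt(minimum, small_sequence, md=md)
        def total(c):
            return efn(c.coords) + 0.5 * (c.velocities ** 2).sum()
        energies = [total(c) for c in traj]
        drift = abs(energies[-1] - energies[0]) / 10  # per bead
        assert drift < 1e-4

    def test_fixed_seed_reproducible(self, small_sequence,
                                     random_conformation):
        md = MDConfig(temperature=0.5, duration=0.5, seed=11)
        t1 = run_md_nvt(random_conformation, small_sequence, md=md)
        t2 = run_md_nvt(random_conformation, small_sequence, md=md)
        assert np.array_equal(t1[-1].coords, t2[-1].coords)

    def test_equipartition_at_temperature(self, small_sequence):
        minimum, _ = anneal_to_minimum(extended_chain(10), small_sequence,
                                       seed=2)
        temp = 0.5
        md = MDConfig(temperature=temp, collision_rate=0.01, duration=50.0,
                      seed=4, sample_every=100)
        traj = run_md_nvt(minimum, small_sequence, md=md)
        ke = np.mean([(0.5 * (c.velocities ** 2).sum()) / 10
                      for c in traj[len(traj) // 2:]])
        assert ke == pytest.approx(1.5 * temp, rel=0.05)

    def test_divergence_aborts_with_diagnostic(self, small_sequence,
                                               random_conformation):
        md = MDConfig(dt=0.5, temperature=10.0, duration=50.0, seed=1,
                      energy_bound=1e4)
        with pytest.raises(EnergyDivergenceError):
            run_md_nvt(random_conformation, small_sequence, md=md)


class TestAnneal:
    def test_final_energy_not_above_start_for_tiny_temperature(
            self, small_sequence):
        minimum, e0 = anneal_to_minimum(extended_chain(10), small_sequence,
                                        seed=2)
        again, e1 = anneal_to_minimum(minimum, small_sequence,
                                      start_T=1e-6, stage_duration=0.1,
                                      seed=3)
        assert e1 <= e0 + 1e-9

    def test_reproducible_for_fixed_seed(self, small_sequence):
        a = anneal_to_minimum(extended_chain(10), small_sequence, seed=9,
                              stage_duration=1.0)
        b = anneal_to_minimum(extended_chain(10), small_sequence, seed=9,
                              stage_duration=1.0)
        assert a[1] == b[1]
        assert np.array_equal(a[0].coords, b[0].coords)

    def test_matches_dense_random_restart_oracle_on_tiny_chain(self):
        """4-bead all-B chain: annealing finds the global minimum located
        by dense random-restart minimization."""
        seq = BeadSequence("BBBB", "T")
        efn, ffn = make_bln_callables(seq)
        rng = np.random.default_rng(0)
        best_oracle = np.inf
        for _ in range(300):
            coords = rng.normal(scale=2.5, size=(4, 3)) \
                + np.arange(4)[:, None] * [3.0, 0, 0]
            _, e, _ = minimize_geometry(Conformation(coords), efn, ffn)
            best_oracle = min(best_oracle, e)
        best_anneal = min(
            anneal_to_minimum(extended_chain(4), seq, stage_duration=1.0,
                              seed=s)[1]
            for s in range(20))
        assert best_anneal == pytest.approx(best_oracle, abs=1e-6)

    def test_compact_minimum_beats_extended_chain_for_hydrophobic_chain(
            self):
        seq = BeadSequence("BBBBBBBB", "TTTTT")
        efn, _ = make_bln_callables(seq)
        e_ext = efn(extended_chain(8).coords)
        _, e_min = anneal_to_minimum(extended_chain(8), seq,
                                     stage_duration=2.0, seed=0)
        assert e_min < e_ext
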