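"""Order parameters, Fréchet distances, clustering, pruning, TM-score."""

import numpy as np
import pytest

from gdsfold.analysis import (chi_order_parameter, cluster_paths,
                              discrete_frechet, native_pair_set,
                              prune_transition_segment,
                              select_low_energy_paths, tm_score)
from gdsfold.bln import Conformation
from gdsfold.fixtures import extended_chain
from gdsfold.gds import FoldingPath, GraphSequence
from gdsfold.contacts import map_from_conformation


def _pairs(n=4):
    return np.array([[0, 3], [0, 4], [1, 4], [1, 5]])[:n]


class TestChi:
    def test_folded_against_itself_is_one(self, rng):
        coords = rng.normal(scale=4, size=(8, 3))
        folded = Conformation(coords)
        assert chi_order_parameter(folded, folded, _pairs()) == 1.0

    def test_all_pairs_displaced_beyond_tolerance_is_zero(self, rng):
        coords = rng.normal(scale=4, size=(8, 3))
        folded = Conformation(coords)
        blown = Conformation(coords * 3.0)
        assert chi_order_parameter(blown, folded, _pairs(),
                                   tolerance=0.5) == 0.0

    def test_half_the_pairs_within_tolerance(self):
        folded = Conformation(np.array(
            [[0, 0, 0], [4, 0, 0], [8, 0, 0], [4, 3, 0], [8, 3, 0],
             [12, 3, 0], [12, 0, 0], [16, 0, 0]], dtype=float))
        moved = folded.coords.copy()
        moved[4] += [0, 5.0, 0]  # displaces only pairs that involve bead 4
        conf = Conformation(moved)
        pairs = np.array([[0, 3], [2, 3], [0, 4], [1, 4]])
        chi = chi_order_parameter(conf, folded, pairs, tolerance=0.5)
        r0 = np.linalg.norm(folded.coords[pairs[:, 0]]
                            - folded.coords[pairs[:, 1]], axis=-1)
        r1 = np.linalg.norm(conf.coords[pairs[:, 0]]
                            - conf.coords[pairs[:, 1]], axis=-1)
        expected = np.mean(np.abs(r1 - r0) < 0.5)
        assert chi == pytest.approx(expected)
        assert chi == 0.5

    def test_monotone_under_inflating_deviations(self, rng):
        base = extended_chain(12)
        folded = Conformation(base.coords * 0.8)
        pairs = np.array([[0, 5], [1, 7], [2, 9], [3, 11]])
        chis = []
        for lam in (0.0, 0.5, 1.0, 2.0):
            conf = Conformation(folded.coords
                                + lam * (base.coords - folded.coords))
            chis.append(chi_order_parameter(conf, folded, pairs,
                                            tolerance=2.0))
        assert all(a >= b for a, b in zip(chis, chis[1:]))

    def test_empty_pair_set_rejected(self, rng):
        conf = Conformation(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            chi_order_parameter(conf, conf, np.empty((0, 2)))


class TestFrechet:
    def test_identity_and_single_points(self):
        track = np.array([[0.1, 0.2], [0.4, 0.5], [0.9, 0.8]])
        assert discrete_frechet(track, track) == 0.0
        a, b = np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])
        assert discrete_frechet(a, b) == pytest.approx(5.0)

    def test_matches_exhaustive_coupling_enumeration(self, rng):
        def brute(a, b):
            na, nb = len(a), len(b)
            d = np.linalg.norm(a[:, None] - b[None, :], axis=-1)
            best = np.inf
            # enumerate all monotone couplings as lattice paths
            def walk(i, j, cur):
                nonlocal best
                cur = max(cur, d[i, j])
                if cur >= best:
                    return
                if i == na - 1 and j == nb - 1:
                    best = min(best, cur)
                    return
                if i + 1 < na:
                    walk(i + 1, j, cur)
                if j + 1 < nb:
                    walk(i, j + 1, cur)
                if i + 1 < na and j + 1 < nb:
                    walk(i + 1, j + 1, cur)
            walk(0, 0, 0.0)
            return best
        for _ in range(50):
            a = rng.random((3, 2))
            b = rng.random((3, 2))
            assert discrete_frechet(a, b) == pytest.approx(brute(a, b))

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(300):
            a, b, c = (rng.random((int(rng.integers(2, 6)), 2))
                       for _ in range(3))
            assert discrete_frechet(a, c) <= \
                discrete_frechet(a, b) + discrete_frechet(b, c) + 1e-12

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            discrete_frechet(np.empty((0, 2)), np.ones((2, 2)))


def _mk_path(pid, de):
    g = map_from_conformation(extended_chain(5))
    p = FoldingPath(sequence=GraphSequence([g, g.copy()]), seed=0,
                    objective=0.0, trace=np.zeros(1), path_id=pid)
    p.floored_energy = de
    return p


class TestSelection:
    def test_empty_request(self):
        assert select_low_energy_paths([_mk_path(0, 1.0)], n=0) == []

    def test_ties_broken_by_identifier(self):
        paths = [_mk_path(pid, 2.0) for pid in (3, 1, 2)]
        out = select_low_energy_paths(paths, n=2)
        assert [p.path_id for p in out] == [1, 2]

    def test_matches_sort_then_slice_oracle(self, rng):
        des = rng.random(20)
        paths = [_mk_path(i, float(de)) for i, de in enumerate(des)]
        out = select_low_energy_paths(paths, n=7)
        expected = list(np.argsort(des)[:7])
        assert [p.path_id for p in out] == expected

    def test_overlong_request_warns_and_returns_all(self):
        paths = [_mk_path(i, float(i)) for i in range(3)]
        with pytest.warns(RuntimeWarning):
            out = select_low_energy_paths(paths, n=10)
        assert len(out) == 3


class TestClustering:
    def test_two_planted_bundles_recovered(self, rng):
        t = np.linspace(0, 1, 6)
        tracks = []
        for _ in range(10):  # beta1 first
            tracks.append(np.column_stack([
                np.clip(2 * t, 0, 1), np.clip(2 * t - 1, 0, 1)])
                + rng.normal(scale=0.02, size=(6, 2)))
        for _ in range(10):  # beta2 first
            tracks.append(np.column_stack([
                np.clip(2 * t - 1, 0, 1), np.clip(2 * t, 0, 1)])
                + rng.normal(scale=0.02, size=(6, 2)))
        for _ in range(4):  # scattered noise
            tracks.append(rng.random((6, 2)))
        n = len(tracks)
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dmat[i, j] = dmat[j, i] = discrete_frechet(tracks[i],
                                                           tracks[j])
        labels = cluster_paths(dmat, min_cluster_size=5)
        found = set(labels) - {-1}
        assert len(found) == 2
        first = {labels[i] for i in range(10)}
        second = {labels[i] for i in range(10, 20)}
        assert first != second

    def test_identical_tracks_form_single_cluster(self):
        dmat = np.zeros((8, 8))
        labels = cluster_paths(dmat, min_cluster_size=3)
        assert len(set(labels)) == 1 and labels[0] != -1

    def test_single_path_is_noise(self):
        assert list(cluster_paths(np.zeros((1, 1)))) == [-1]


class TestPruning:
    def test_entirely_folded_track_is_empty(self):
        track = np.full((5, 2), 0.95)
        with pytest.warns(RuntimeWarning):
            seg = prune_transition_segment(track)
        assert len(seg) == 0

    def test_single_crossing(self):
        track = np.array([[0.1, 0.1], [0.3, 0.2], [0.5, 0.6], [0.9, 0.85],
                          [0.95, 0.95]])
        seg = prune_transition_segment(track)
        assert np.array_equal(seg, track[1:4])

    def test_reentry_anchors_at_last_exit(self):
        track = np.array([[0.1, 0.1], [0.6, 0.5], [0.2, 0.3], [0.5, 0.6],
                          [0.9, 0.9]])
        seg = prune_transition_segment(track)
        assert np.array_equal(seg, track[2:5])


class TestTMScore:
    def test_rigid_motion_scores_one(self, rng):
        from scipy.spatial.transform import Rotation
        coords = rng.normal(scale=8, size=(30, 3))
        rot = Rotation.random(random_state=np.random.RandomState(1))
        moved = coords @ rot.as_matrix().T + [4.0, 5.0, -6.0]
        assert tm_score(Conformation(coords), Conformation(moved)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_d0_closed_form_at_56_residues(self):
        d0 = 1.24 * (56 - 15) ** (1 / 3) - 1.8
        assert d0 == pytest.approx(2.476, abs=2e-3)

    def test_short_chain_clamps_d0_with_warning(self, rng):
        a = Conformation(rng.normal(size=(10, 3)))
        b = Conformation(rng.normal(size=(10, 3)))
        with pytest.warns(RuntimeWarning):
            s = tm_score(a, b)
        assert 0.0 < s <= 1.0

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            tm_score(Conformation(rng.normal(size=(5, 3))),
                     Conformation(rng.normal(size=(6, 3))))


class TestNativePairs:
    def test_restricted_to_range_and_contact(self):
        conf = extended_chain(20)
        coords = conf.coords.copy()
        coords[6] = coords[0] + [4.0, 1.0, 0.0]  # long-range contact 0-6
        conf = Conformation(coords)
        pairs = native_pair_set(conf, (0, 10))
        assert all(0 <= i and j < 10 and j - i >= 3 for i, j in pairs)
        assert [0, 6] in pairs.tolist()
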