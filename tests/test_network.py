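"""Contact network construction, communities, paths, hydrogen bonds."""

import itertools

import networkx as nx
import numpy as np
import pytest

from bfekit.core import Bond, MolecularSystem, Trajectory
from bfekit.network import (build_network, contact_adjacency,
                            displacement_correlation, girvan_newman,
                            hbond_occupancy, optimal_path, rand_index)
from bfekit.synth import make_correlated_trajectory

from conftest import enumerate_simple_paths, make_atom


class TestCorrelation:
    def test_identical_motion_gives_unit_correlation(self, rng):
        base = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 4.0, 0], [4, 4, 0]])
        disp = rng.normal(0, 0.5, (50, 1, 3))
        frames = base[None] + disp  # every atom moves identically
        C = displacement_correlation(Trajectory(frames), [0, 1, 2, 3], fit=False)
        np.testing.assert_allclose(C, 1.0, atol=1e-12)

    def test_independent_noise_gives_small_correlation(self, rng):
        base = np.zeros((4, 3))
        frames = base[None] + rng.normal(0, 0.5, (10000, 4, 3))
        C = displacement_correlation(Trajectory(frames), [0, 1, 2, 3], fit=False)
        off = C[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_matches_covariance_oracle(self, rng):
        # planted latent factor: x_i(t) = mu_i + a_i s(t) + noise
        n, F = 5, 400
        mu = rng.uniform(0, 10, (n, 3))
        a = rng.normal(0, 1, (n, 3))
        s = rng.normal(0, 1, F)
        frames = mu[None] + a[None] * s[:, None, None] + \
            rng.normal(0, 0.2, (F, n, 3))
        C = displacement_correlation(Trajectory(frames), list(range(n)), fit=False)
        # direct covariance formula
        x = frames - frames.mean(axis=0)
        oracle = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                num = np.mean(np.sum(x[:, i] * x[:, j], axis=1))
                den = np.sqrt(np.mean(np.sum(x[:, i] ** 2, axis=1))
                              * np.mean(np.sum(x[:, j] ** 2, axis=1)))
                oracle[i, j] = num / den
        np.testing.assert_allclose(C, oracle, atol=1e-10)

    def test_symmetry_and_bounds(self):
        _, traj, _ = make_correlated_trajectory(seed=8)
        C = displacement_correlation(traj, list(range(traj.n_atoms)))
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
        assert np.abs(C).max() <= 1 + 1e-12

    def test_zero_variance_node_rejected(self):
        frames = np.zeros((20, 2, 3))
        frames[:, 1] = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="zero-variance"):
            displacement_correlation(Trajectory(frames), [0, 1], fit=False)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="10 frames"):
            displacement_correlation(Trajectory(np.zeros((5, 3, 3))), [0, 1, 2])


class TestContacts:
    def _two_residue(self, distance):
        atoms = [make_atom(0, "CA", "C", 1), make_atom(1, "CA", "C", 2)]
        s = MolecularSystem(atoms)
        f = np.array([[0.0, 0, 0], [distance, 0, 0]])
        return s, f

    def test_permanent_contact(self):
        s, f = self._two_residue(3.0)
        adj, occ, _ = contact_adjacency(s, Trajectory(np.repeat(f[None], 5, 0)))
        assert adj[0, 1] and occ[0, 1] == 1.0

    def test_permanent_separation(self):
        s, f = self._two_residue(20.0)
        adj, occ, _ = contact_adjacency(s, Trajectory(np.repeat(f[None], 5, 0)))
        assert not adj[0, 1] and occ[0, 1] == 0.0

    def test_fluctuating_pair_against_counting_oracle(self):
        s, f = self._two_residue(4.0)
        # 60% of frames inside the cutoff, occupancy_min 0.75 -> no edge
        frames = np.array([f if k % 5 < 3 else f + [[0, 0, 0], [2.0, 0, 0]]
                           for k in range(100)])
        adj, occ, _ = contact_adjacency(s, Trajectory(frames),
                                        occupancy_min=0.75)
        assert occ[0, 1] == pytest.approx(0.6)
        assert not adj[0, 1]

    def test_calpha_strict_uses_node_atoms_only(self):
        # CB atoms touch but CA atoms are 6 A apart
        atoms = [make_atom(0, "CA", "C", 1), make_atom(1, "CB", "C", 1),
                 make_atom(2, "CA", "C", 2), make_atom(3, "CB", "C", 2)]
        s = MolecularSystem(atoms)
        f = np.array([[0.0, 0, 0], [2.0, 0, 0], [6.0, 0, 0], [4.0, 0, 0]])
        traj = Trajectory(np.repeat(f[None], 3, 0))
        adj_default, _, _ = contact_adjacency(s, traj)
        adj_strict, _, _ = contact_adjacency(s, traj, calpha_strict=True)
        assert adj_default[0, 1]
        assert not adj_strict[0, 1]


class TestBuildNetwork:
    def test_edge_weight_formula(self):
        C = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, -0.5], [0.1, -0.5, 1.0]])
        adj = np.array([[False, True, True], [True, False, True],
                        [True, True, False]])
        g = build_network(C, adj).graph
        assert g[0][1]["d"] == pytest.approx(0.0)
        assert g[0][2]["d"] == pytest.approx(-np.log(0.1))
        # negative correlation enters by magnitude, sign kept on the c attr
        assert g[1][2]["d"] == pytest.approx(-np.log(0.5))
        assert g[1][2]["c"] == -0.5

    def test_adjacency_gates_edges(self):
        C = np.full((3, 3), 0.99)
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 0] = True
        g = build_network(C, adj).graph
        assert g.has_edge(0, 1) and not g.has_edge(0, 2)

    def test_weights_nonnegative_and_decreasing_in_c(self):
        cs = np.array([0.1, 0.5, 0.9, 0.999])
        ds = []
        for c in cs:
            C = np.array([[1, c], [c, 1.0]])
            adj = ~np.eye(2, dtype=bool)
            ds.append(build_network(C, adj).graph[0][1]["d"])
        assert all(d >= 0 for d in ds)
        assert all(a > b for a, b in zip(ds, ds[1:]))


class TestCommunities:
    def test_two_cliques_with_bridge_split_at_bridge(self):
        g = nx.Graph()
        for base in (0, 5):
            for i, j in itertools.combinations(range(base, base + 5), 2):
                g.add_edge(i, j, d=0.05)
        g.add_edge(4, 5, d=1.0)
        part = girvan_newman(g)
        assert part.n_communities == 2
        labels = part.labels(range(10))
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[9]
        # oracle: best 2-partition by exhaustive modularity
        best_q, best_cut = max(
            (nx.community.modularity(g, [set(c), set(g) - set(c)]), set(c))
            for r in range(1, 5)
            for c in itertools.combinations(sorted(g), r))
        assert part.modularity >= best_q - 1e-9

    def test_uniform_clique_single_community(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 0.1, "d")
        part = girvan_newman(g)
        assert part.n_communities == 1

    def test_planted_three_block_graph_recovered(self):
        rng = np.random.default_rng(99)
        g = nx.Graph()
        labels = {}
        for b in range(3):
            for i in range(8):
                labels[b * 8 + i] = b
        for i, j in itertools.combinations(range(24), 2):
            p = 0.9 if labels[i] == labels[j] else 0.05
            if rng.random() < p:
                g.add_edge(i, j, d=0.1)
        part = girvan_newman(g)
        ri = rand_index(part.labels(range(24)),
                        [labels[i] for i in range(24)])
        assert ri >= 0.9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            girvan_newman(nx.Graph())


class TestPipelineRecovery:
    @pytest.mark.parametrize("groups", [(9, 9), (9, 9, 9)])
    def test_planted_communities_recovered(self, groups):
        system, traj, labels = make_correlated_trajectory(seed=1,
                                                          group_sizes=groups)
        nodes = list(range(system.n_atoms))
        C = displacement_correlation(traj, nodes)
        adj, occ, _ = contact_adjacency(system, traj)
        graph = build_network(C, adj, node_ids=nodes, occupancy=occ)
        part = girvan_newman(graph)
        assert rand_index(part.labels(nodes), labels) >= 0.9


class TestPaths:
    def _random_graph(self, seed, n):
        rng = np.random.default_rng(seed)
        edges = {}
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.55:
                edges[(i, j)] = float(rng.uniform(0.1, 2.0))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for (i, j), w in edges.items():
            g.add_edge(i, j, d=w)
        return g, edges

    def test_direct_edge_beats_detour(self):
        g = nx.Graph()
        g.add_edge(0, 1, d=0.2)
        g.add_edge(0, 2, d=1.0)
        g.add_edge(2, 1, d=1.0)
        paths = optimal_path(g, 0, 1)
        assert paths[0].nodes == [0, 1]
        assert paths[0].total_weight == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        g, edges = self._random_graph(seed, 8)
        if not nx.has_path(g, 0, 7):
            assert optimal_path(g, 0, 7) == []
            return
        got = optimal_path(g, 0, 7, n_suboptimal=2)
        all_paths = sorted(enumerate_simple_paths(edges, 0, 7))
        assert got[0].total_weight == pytest.approx(all_paths[0][0], abs=1e-12)
        for k, p in enumerate(got):
            assert p.total_weight == pytest.approx(all_paths[k][0], abs=1e-12)

    def test_source_equals_sink(self):
        g = nx.Graph()
        g.add_edge(0, 1, d=1.0)
        paths = optimal_path(g, 0, 0)
        assert paths[0].nodes == [0] and paths[0].total_weight == 0.0

    def test_disconnected_yields_no_path(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        assert optimal_path(g, 0, 1) == []


class TestHBonds:
    def _oh_o_system(self):
        atoms = [make_atom(0, "O1", "O", 1), make_atom(1, "H1", "H", 1, rmh=0.6),
                 make_atom(2, "O2", "O", 2)]
        return MolecularSystem(atoms, bonds=[Bond(0, 1, 500.0, 1.0)])

    def _linear_frame(self, d_oo):
        return np.array([[0.0, 0, 0], [1.0, 0, 0], [d_oo, 0, 0]])

    def test_linear_geometry_detected_every_frame(self):
        s = self._oh_o_system()
        traj = Trajectory(np.repeat(self._linear_frame(2.8)[None], 10, 0))
        series = hbond_occupancy(s, traj, {0}, {2})
        assert len(series) == 1
        assert series[0].occupancy == 1.0

    def test_long_distance_never_detected(self):
        s = self._oh_o_system()
        traj = Trajectory(np.repeat(self._linear_frame(4.0)[None], 10, 0))
        assert hbond_occupancy(s, traj, {0}, {2}) == []

    def test_constructed_series_counts_exact_frames(self):
        # bond formed in exactly 927 of 2000 frames
        s = self._oh_o_system()
        near = self._linear_frame(2.8)
        far = self._linear_frame(5.0)
        formed = np.zeros(2000, bool)
        formed[np.random.default_rng(4).choice(2000, 927, replace=False)] = True
        frames = np.array([near if ok else far for ok in formed])
        series = hbond_occupancy(s, Trajectory(frames), {0}, {2})
        assert series[0].n_frames_detected == 927
        assert series[0].occupancy == pytest.approx(927 / 2000)

    def test_occupancy_invariant_to_frame_order(self):
        s = self._oh_o_system()
        near, far = self._linear_frame(2.8), self._linear_frame(5.0)
        frames = np.array([near, far, near, near, far])
        o1 = hbond_occupancy(s, Trajectory(frames), {0}, {2})[0].occupancy
        o2 = hbond_occupancy(s, Trajectory(frames[::-1]), {0}, {2})[0].occupancy
        assert o1 == o2

    def test_angle_criterion_rejects_bent_geometry(self):
        s = self._oh_o_system()
        # acceptor at 90 degrees from the O-H axis, still within distance
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]])
        assert hbond_occupancy(s, Trajectory(frame[None]), {0}, {2}) == []

    def test_donor_without_hydrogen_rejected(self):
        atoms = [make_atom(0, "O1", "O", 1), make_atom(1, "O2", "O", 2)]
        s = MolecularSystem(atoms)
        with pytest.raises(ValueError, match="hydrogen"):
            hbond_occupancy(s, Trajectory(np.zeros((1, 2, 3)) + [[0, 0, 0], [3, 0, 0]]),
                            {0}, {1})


def test_rand_index_basics():
    assert rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0
    assert rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(2 / 6)
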