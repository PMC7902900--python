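"""DCCM, network construction, community detection and path enumeration."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdpost as mp
from mdpost.errors import (
    ParameterError,
    UndefinedStatisticError,
    UnreachableError,
)
from mdpost.network import CorrelationMatrix, edge_weight, network_from_edges


def uniform_correlation(n, value=0.5):
    c = np.full((n, n), value)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c, [("A", i + 1) for i in range(n)])


class TestDccm:
    def test_unit_diagonal(self, toy_topology):
        traj, _ = mp.sample_correlated_trajectory(toy_topology, np.eye(5), 200, seed=0)
        c = mp.dccm(traj)
        assert np.all(np.diag(c.values) == 1.0)

    def test_rigid_translation_mode_dominates(self, toy_topology, rng):
        # a shared displacement stream drives all atoms -> correlations -> 1
        base = rng.normal(size=(2000, 1, 3)) * 5.0
        noise = rng.normal(size=(2000, 5, 3)) * 0.01
        coords = np.zeros((2000, 5, 3)) + base + noise
        c = mp.dccm(mp.Trajectory(toy_topology, coords))
        assert c.values.min() > 0.99

    def test_prescribed_correlation_recovered(self, toy_topology):
        n = 50_000
        cov = np.eye(5)
        cov[1, 3] = cov[3, 1] = 0.6
        traj, truth = mp.sample_correlated_trajectory(toy_topology, cov, n, seed=5)
        c = mp.dccm(traj)
        assert c.values[1, 3] == pytest.approx(0.6, abs=0.02)
        assert np.abs(c.values - truth.true_correlation).max() <= 3 / np.sqrt(n)

    def test_frame_order_invariance(self, toy_topology, rng):
        traj, _ = mp.sample_correlated_trajectory(toy_topology, np.eye(5), 300, seed=1)
        perm = rng.permutation(300)
        c1 = mp.dccm(traj)
        c2 = mp.dccm(mp.Trajectory(toy_topology, traj.coords[perm]))
        assert c1.values == pytest.approx(c2.values, abs=1e-12)

    def test_immobile_atom_rejected_by_name(self, toy_topology):
        coords = np.zeros((10, 5, 3))
        coords[:, :4, :] = np.random.default_rng(0).normal(size=(10, 4, 3))
        with pytest.raises(UndefinedStatisticError, match="id 5"):
            mp.dccm(mp.Trajectory(toy_topology, coords))


class TestMask:
    def test_boundary_is_strict(self):
        c = np.eye(4)
        vals = {(0, 1): 0.25, (0, 2): 0.299, (1, 2): 0.301, (1, 3): 0.35}
        for (i, j), v in vals.items():
            c[i, j] = c[j, i] = v
        cm = CorrelationMatrix(c, [("A", i + 1) for i in range(4)])
        masked = mp.mask_dccm(cm, threshold=0.3)
        assert masked.mask[0, 1] and masked.mask[0, 2]
        assert not masked.mask[1, 2] and not masked.mask[1, 3]

    def test_exact_threshold_survives(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = 0.3
        cm = CorrelationMatrix(c, [("A", 1), ("A", 2)])
        assert not mp.mask_dccm(cm, 0.3).mask[0, 1]

    def test_zero_threshold_masks_nothing(self):
        cm = uniform_correlation(3, 0.01)
        assert not mp.mask_dccm(cm, 0.0).mask.any()

    def test_mask_preserves_symmetry(self, rng):
        c = rng.uniform(-1, 1, size=(6, 6))
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 1.0)
        cm = CorrelationMatrix(c, [("A", i + 1) for i in range(6)])
        m = mp.mask_dccm(cm, 0.3).mask
        assert np.array_equal(m, m.T)

    def test_threshold_out_of_range(self):
        with pytest.raises(ParameterError):
            mp.mask_dccm(uniform_correlation(2), threshold=1.5)


class TestBuildNetwork:
    def contact_traj(self, fraction, contact=4.4, n_frames=1000):
        top = mp.build_toy_system(mp.SyntheticSpec(n_residues=4, seed=0))
        traj, _ = mp.sample_contact_schedule(
            top, {(("A", 1), ("A", 3)): fraction}, contact_distance=contact,
            apart_distance=10.0, n_frames=n_frames, seed=3,
        )
        return traj

    @pytest.mark.parametrize(
        "fraction,expected", [(0.749, False), (0.750, True), (0.751, True)]
    )
    def test_persistence_boundary_inclusive(self, fraction, expected):
        traj = self.contact_traj(fraction)
        net = mp.build_network(traj, uniform_correlation(4))
        assert net.graph.has_edge(0, 2) is expected

    @pytest.mark.parametrize(
        "distance,expected", [(4.49, True), (4.50, True), (4.51, False)]
    )
    def test_distance_boundary_inclusive(self, distance, expected):
        traj = self.contact_traj(1.0, contact=distance, n_frames=100)
        net = mp.build_network(traj, uniform_correlation(4))
        assert net.graph.has_edge(0, 2) is expected

    def test_sequence_adjacent_pairs_excluded(self):
        top = mp.build_toy_system(mp.SyntheticSpec(n_residues=3, seed=0))
        coords = np.tile(
            np.array([[[0.0, 0, 0], [3.0, 0, 0], [0.0, 3, 0]]]), (10, 1, 1)
        )
        traj = mp.Trajectory(top, coords)
        net = mp.build_network(traj, uniform_correlation(3))
        assert not net.graph.has_edge(0, 1)  # adjacent in sequence
        assert net.graph.has_edge(0, 2)      # |i-j| = 2, within 4.5 Å

    def test_edge_weight_convention(self):
        assert edge_weight(1.0) == 0.0
        assert edge_weight(np.exp(-1.0)) == pytest.approx(1.0)
        assert edge_weight(-np.exp(-1.0)) == pytest.approx(1.0)  # |C| is used
        assert edge_weight(0.0) == pytest.approx(-np.log(1e-6))

    def test_edges_subset_of_persistent_pairs(self):
        traj = self.contact_traj(0.9)
        frac, _keys = mp.residue_contact_fractions(traj, cutoff=4.5)
        net = mp.build_network(traj, uniform_correlation(4))
        for u, v in net.graph.edges:
            assert frac[u, v] >= 0.75


class TestCommunities:
    def two_clique_bridge(self, intra=0.8, bridge=0.2):
        edges = []
        for clique in ([0, 1, 2, 3, 4], [5, 6, 7, 8, 9]):
            for i, j in itertools.combinations(clique, 2):
                edges.append((i, j, intra))
        edges.append((4, 5, bridge))
        return network_from_edges(10, edges)

    def test_two_cliques_split(self):
        part = mp.detect_communities(self.two_clique_bridge())
        assert part.communities == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]

    def test_matches_bruteforce_modularity_over_bipartitions(self):
        net = self.two_clique_bridge()
        g = net.graph
        best_q = -np.inf
        for r in range(1, 6):
            for left in itertools.combinations(range(10), r):
                parts = [set(left), set(range(10)) - set(left)]
                q = nx.community.modularity(g, parts, weight="affinity")
                best_q = max(best_q, q)
        part = mp.detect_communities(net)
        assert part.modularity == pytest.approx(best_q, abs=1e-9)

    def test_complete_graph_single_community(self):
        edges = [(i, j, 0.7) for i, j in itertools.combinations(range(6), 2)]
        part = mp.detect_communities(network_from_edges(6, edges))
        assert len(part.communities) == 1

    def test_modularity_beats_trivial_partition(self):
        net = self.two_clique_bridge()
        part = mp.detect_communities(net)
        trivial = nx.community.modularity(
            net.graph, [set(range(10))], weight="affinity"
        )
        assert part.modularity >= trivial

    def test_edgeless_graph_singletons(self):
        part = mp.detect_communities(network_from_edges(4, []))
        assert part.communities == [[0], [1], [2], [3]]

    def test_intercommunity_connectivity_on_bridge(self):
        part = mp.detect_communities(self.two_clique_bridge())
        assert part.connectivity.shape == (2, 2)
        assert part.connectivity[0, 1] > 0
        assert np.all(np.diag(part.connectivity) == 0)

    def test_two_domain_trajectory_communities_separate_domains(self):
        # two compact 5-residue domains with strong internal correlation and
        # one weakly correlated linker contact between them
        top = mp.build_toy_system(mp.SyntheticSpec(n_residues=10, seed=0))
        cluster = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [1.0, 1.0, 0]]
        )  # compact: all pairwise distances <= 1.74 Å
        ref = np.vstack([cluster, cluster + np.array([5.0, 0, 0])])
        cov = 0.01 * np.eye(10)
        for dom in (range(5), range(5, 10)):
            for i in dom:
                for j in dom:
                    if i != j:
                        cov[i, j] = 0.009
        cov[4, 5] = cov[5, 4] = 0.001           # weak inter-domain coupling
        traj, _ = mp.sample_correlated_trajectory(
            top, cov, 2000, seed=9, reference=ref
        )
        c = mp.dccm(traj)
        net = mp.build_network(traj, c, contact_cutoff=4.5, persistence=0.75)
        part = mp.detect_communities(net)
        labels = [part.node_labels[n] for n in range(10)]
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[9]


class TestPaths:
    def test_chain_graph_optimal(self):
        net = network_from_edges(
            3, [(0, 1, np.exp(-1.0)), (1, 2, np.exp(-1.0))]
        )
        ps = mp.paths(net, 0, 2)
        assert ps.optimal_path == (0, 1, 2)
        assert ps.optimal_length == pytest.approx(2.0)

    def test_zero_tolerance_only_optimal(self):
        # square with one diagonal: two equal-length two-hop routes
        w = np.exp(-1.0)
        net = network_from_edges(
            4, [(0, 1, w), (1, 3, w), (0, 2, w), (2, 3, w), (0, 3, w * w * 0.5)]
        )
        ps = mp.paths(net, 0, 3, tolerance=0.0)
        lengths = [l for l, _ in ps.paths]
        assert all(l == pytest.approx(ps.optimal_length) for l in lengths)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(17)
        checked = 0
        for trial in range(50):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges:
                g.edges[u, v]["c"] = float(rng.uniform(0.05, 0.95))
            net = network_from_edges(
                n, [(u, v, g.edges[u, v]["c"]) for u, v in g.edges]
            )
            src, dst = 0, n - 1
            if not nx.has_path(net.graph, src, dst):
                with pytest.raises(UnreachableError):
                    mp.paths(net, src, dst, tolerance=3.0)
                continue
            tol = float(rng.uniform(0.0, 4.0))
            ps = mp.paths(net, src, dst, tolerance=tol)
            # oracle: enumerate every simple path and filter by length
            all_paths = []
            for p in nx.all_simple_paths(net.graph, src, dst):
                length = sum(
                    net.graph.edges[a, b]["weight"] for a, b in zip(p, p[1:])
                )
                all_paths.append((length, tuple(p)))
            l_opt = min(l for l, _ in all_paths)
            expected = sorted(
                (l, p) for l, p in all_paths if l <= l_opt + tol + 1e-12
            )
            assert [p for _, p in ps.paths] == [p for _, p in expected]
            assert [l for l, _ in ps.paths] == pytest.approx(
                [l for l, _ in expected]
            )
            checked += 1
        assert checked >= 30

    def test_floyd_warshall_agrees_with_dijkstra(self):
        rng = np.random.default_rng(23)
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        edges = [(u, v, float(rng.uniform(0.1, 0.9))) for u, v in g.edges]
        net = network_from_edges(30, edges)
        from mdpost.network import _all_pairs_shortest

        dist, nodes = _all_pairs_shortest(net)
        pos = {n: i for i, n in enumerate(nodes)}
        for _ in range(100):
            a, b = rng.integers(0, 30, size=2)
            if a == b:
                continue
            try:
                d = nx.dijkstra_path_length(net.graph, int(a), int(b))
            except nx.NetworkXNoPath:
                assert not np.isfinite(dist[pos[int(a)], pos[int(b)]])
                continue
            assert dist[pos[int(a)], pos[int(b)]] == pytest.approx(d, abs=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 1 << 20))
    def test_suboptimal_count_monotone_in_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(7, 0.6, seed=seed % (1 << 16))
        net = network_from_edges(
            7, [(u, v, float(rng.uniform(0.1, 0.9))) for u, v in g.edges]
        )
        if not (0 in net.graph and nx.has_path(net.graph, 0, 6)):
            return
        counts = [
            mp.paths(net, 0, 6, tolerance=t).n_paths for t in (0.0, 1.0, 3.0, 8.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_same_source_sink_rejected(self):
        net = network_from_edges(2, [(0, 1, 0.5)])
        with pytest.raises(ParameterError):
            mp.paths(net, 0, 0)
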