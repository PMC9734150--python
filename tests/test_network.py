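"""Residue networks: graph construction, Dijkstra, SPM, CPL, node weakening."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from allonet import (CorrelationMatrix, EnsembleTrajectory, ResidueGraph,
                     build_residue_graph, characteristic_path_length,
                     compute_spm, node_weakening, shortest_path)
from allonet.network import MIN_EDGE_LENGTH, NetworkError


def _graph(edges) -> ResidueGraph:
    """ResidueGraph from (u, v, length) triples."""
    g = nx.Graph()
    for u, v, ln in edges:
        g.add_edge(u, v, length=float(ln))
    return ResidueGraph(graph=g)


def _random_graph(seed, max_nodes=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_nodes + 1))
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                g.add_edge(f"n{i}", f"n{j}",
                           length=float(rng.uniform(0.5, 2.0)))
    if g.number_of_edges() == 0:
        g.add_edge("n0", "n1", length=1.0)
    return ResidueGraph(graph=g)


def _brute_force_shortest(g: nx.Graph, s, t):
    """Exhaustive enumeration over all simple paths (oracle)."""
    best_len, best_path = math.inf, None
    for path in nx.all_simple_paths(g, s, t):
        ln = sum(g[a][b]["length"] for a, b in zip(path[:-1], path[1:]))
        if ln < best_len - 1e-12:
            best_len, best_path = ln, path
    return best_len, best_path


def _brute_force_cpl(g: nx.Graph):
    total, pairs = 0.0, 0
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        ln, _ = _brute_force_shortest(g, s, t)
        if math.isfinite(ln):
            total += ln
            pairs += 1
    return total / pairs if pairs else math.nan


class TestBuildResidueGraph:
    def _static_traj(self, coords, labels):
        frames = np.repeat(np.asarray(coords, float)[None], 3, axis=0)
        return EnsembleTrajectory(coords=frames, labels=labels)

    def _corr(self, values, labels):
        return CorrelationMatrix(values=np.asarray(values, float),
                                 labels=labels, n_frames=3)

    def test_edge_lengths_monotone_in_correlation(self):
        labels = ("A:1", "A:2", "A:3")
        traj = self._static_traj([[0, 0, 0], [3, 0, 0], [3, 3, 0]], labels)
        c = self._corr([[1, 0.9, 0.5], [0.9, 1, 0.1], [0.5, 0.1, 1]], labels)
        rg = build_residue_graph(traj, c, contact_cutoff=6.0, corr_min=0.05)
        g = rg.graph
        assert g.number_of_edges() == 3
        assert (g["A:1"]["A:2"]["length"] < g["A:1"]["A:3"]["length"]
                < g["A:2"]["A:3"]["length"])
        assert g["A:1"]["A:2"]["length"] == pytest.approx(-math.log(0.9))

    def test_occupancy_threshold_drops_transient_contact(self):
        labels = ("A:1", "A:2", "A:3")
        frames = np.repeat(
            np.array([[[0, 0, 0], [3, 0, 0], [3, 3, 0]]], float), 4, axis=0)
        frames[0, 2, 1] = 30.0        # pair (1,3)/(2,3) separated in frame 0
        traj = EnsembleTrajectory(coords=frames, labels=labels)
        c = self._corr([[1, 0.9, 0.5], [0.9, 1, 0.4], [0.5, 0.4, 1]], labels)
        rg = build_residue_graph(traj, c, contact_cutoff=6.0,
                                 occupancy_min=1.0)
        assert rg.graph.has_edge("A:1", "A:2")
        assert not rg.graph.has_edge("A:2", "A:3")

    def test_edges_match_bruteforce_recomputation(self):
        rng = np.random.default_rng(17)
        n = 12
        base = rng.uniform(0, 15, size=(n, 3))
        frames = base + 0.5 * rng.standard_normal((40, n, 3))
        labels = tuple(f"A:{i}" for i in range(n))
        traj = EnsembleTrajectory(coords=frames, labels=labels)
        m = rng.uniform(-0.9, 0.9, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        dccm = CorrelationMatrix(values=m, labels=labels, n_frames=40)
        cutoff, occ_min, corr_min = 7.0, 0.5, 0.1
        rg = build_residue_graph(traj, dccm, cutoff, occ_min, corr_min)
        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(frames[:, i] - frames[:, j], axis=1)
                if (d <= cutoff).mean() >= occ_min and abs(m[i, j]) >= corr_min:
                    expected.add((labels[i], labels[j]))
        got = {tuple(sorted(e)) for e in rg.graph.edges}
        assert got == {tuple(sorted(e)) for e in expected}

    def test_perfect_correlation_clamped(self):
        labels = ("A:1", "A:2", "A:3")
        traj = self._static_traj([[0, 0, 0], [3, 0, 0], [3, 3, 0]], labels)
        c = self._corr([[1, 1.0, 0.5], [1.0, 1, 0.4], [0.5, 0.4, 1]], labels)
        rg = build_residue_graph(traj, c)
        assert rg.graph["A:1"]["A:2"]["length"] == MIN_EDGE_LENGTH

    def test_empty_graph_rejected(self):
        labels = ("A:1", "A:2", "A:3")
        traj = self._static_traj([[0, 0, 0], [30, 0, 0], [60, 0, 0]], labels)
        c = self._corr([[1, 0.9, 0.5], [0.9, 1, 0.4], [0.5, 0.4, 1]], labels)
        with pytest.raises(NetworkError, match="no edges"):
            build_residue_graph(traj, c, contact_cutoff=6.0)


class TestShortestPath:
    def test_two_hop_beats_direct_edge(self):
        rg = _graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 3)])
        sp = shortest_path(rg, "A", "C")
        assert sp.path == ("A", "B", "C")
        assert sp.length == pytest.approx(2.0)

    def test_single_edge_graph(self):
        rg = _graph([("A", "B", 0.7)])
        sp = shortest_path(rg, "A", "B")
        assert sp.path == ("A", "B")
        assert sp.length == pytest.approx(0.7)

    def test_unreachable_gives_no_path_result(self):
        rg = _graph([("A", "B", 1), ("C", "D", 1)])
        sp = shortest_path(rg, "A", "C")
        assert not sp.reachable
        assert sp.path is None and math.isinf(sp.length)

    def test_lexicographic_tie_break(self):
        # two equal-length routes A->Z: via B and via C; B wins
        rg = _graph([("A", "B", 1), ("B", "Z", 1), ("A", "C", 1),
                     ("C", "Z", 1)])
        assert shortest_path(rg, "A", "Z").path == ("A", "B", "Z")

    @pytest.mark.parametrize("seed", range(100))
    def test_lengths_match_exhaustive_enumeration(self, seed):
        rg = _random_graph(seed)
        g = rg.graph
        nodes = sorted(g.nodes)
        rng = np.random.default_rng(seed + 1000)
        for _ in range(3):
            s, t = rng.choice(nodes, size=2, replace=False)
            expected_len, _ = _brute_force_shortest(g, s, t)
            sp = shortest_path(rg, s, t)
            assert sp.length == pytest.approx(expected_len)

    def test_triangle_property(self):
        rg = _random_graph(7)
        nodes = sorted(rg.graph.nodes)
        for a, b, c in itertools.permutations(nodes[:4], 3):
            ab = shortest_path(rg, a, b).length
            bc = shortest_path(rg, b, c).length
            ac = shortest_path(rg, a, c).length
            if all(map(math.isfinite, (ab, bc, ac))):
                assert ac <= ab + bc + 1e-9


class TestSpm:
    def test_path_graph_middle_edge_dominates(self):
        rg = _graph([("A", "B", 1), ("B", "C", 1), ("C", "D", 1)])
        spm = compute_spm(rg)
        assert spm.edge_usage[("B", "C")] == pytest.approx(1.0)
        assert spm.edge_usage[("A", "B")] < 1.0

    def test_bridge_between_cliques_has_max_usage(self):
        edges = []
        left = [f"L{i}" for i in range(4)]
        right = [f"R{i}" for i in range(4)]
        for grp in (left, right):
            edges += [(a, b, 1.0) for a, b in itertools.combinations(grp, 2)]
        edges.append(("L0", "R0", 1.0))
        spm = compute_spm(_graph(edges))
        assert spm.edge_usage[("L0", "R0")] == pytest.approx(1.0)
        # pair-counting oracle: bridge carries all 16 cross pairs (x2 ordered),
        # clique edge (L0, Li) carries Li's cross traffic plus the local pair
        assert spm.edge_usage[("L0", "L1")] == pytest.approx(
            (2 * 4 + 2) / (2 * 16))

    def test_threshold_zero_keeps_all_used_edges(self):
        rg = _graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 3)])
        spm = compute_spm(rg, threshold=0.0)
        # the long direct edge lies on no shortest path: zero usage, excluded
        assert spm.edge_usage[("A", "C")] == 0.0
        assert spm.spm_edges == {("A", "B"), ("B", "C")}

    def test_usage_scale_invariant(self):
        rg1 = _random_graph(3)
        scaled = nx.Graph()
        for u, v, d in rg1.graph.edges(data=True):
            scaled.add_edge(u, v, length=d["length"] * 7.5)
        spm1 = compute_spm(rg1)
        spm2 = compute_spm(ResidueGraph(graph=scaled))
        for e in spm1.edge_usage:
            assert spm1.edge_usage[e] == pytest.approx(spm2.edge_usage[e])

    def test_interface_stiffening_adds_intersubunit_spm_edges(self, dimer):
        # regulator binding (stiffened interface) must strengthen
        # cross-subunit communication pathways
        import allonet as al

        net, info = dimer
        stiff = al.perturb_network(net, info["interface"], 5.0)

        def inter_edges(network):
            cov = al.network_covariance(network, mode="scalar")
            traj = al.sample_ensemble(cov, 5000, seed=0)
            d = al.compute_dccm(traj, superpose=False)
            rg = al.build_residue_graph(traj, d)
            spm = al.compute_spm(rg)
            return sum(1 for (u, v) in spm.spm_edges
                       if u.partition(":")[0] != v.partition(":")[0])

        assert inter_edges(stiff) > inter_edges(net)


class TestCpl:
    def test_path_graph_p3(self):
        rg = _graph([("A", "B", 1), ("B", "C", 1)])
        assert characteristic_path_length(rg).cpl == pytest.approx(4 / 3)

    def test_complete_graph_unit_lengths(self):
        nodes = list("ABCDE")
        rg = _graph([(a, b, 1.0) for a, b in itertools.combinations(nodes, 2)])
        res = characteristic_path_length(rg)
        assert res.cpl == pytest.approx(1.0)
        assert res.reachable_fraction == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_all_pairs(self, seed):
        rg = _random_graph(seed + 200)
        expected = _brute_force_cpl(rg.graph)
        assert characteristic_path_length(rg).cpl == pytest.approx(expected)

    def test_uniform_scaling_scales_cpl(self):
        rg = _random_graph(5)
        scaled = nx.Graph()
        for u, v, d in rg.graph.edges(data=True):
            scaled.add_edge(u, v, length=d["length"] * 3.0)
        assert characteristic_path_length(ResidueGraph(graph=scaled)).cpl == \
            pytest.approx(3.0 * characteristic_path_length(rg).cpl)


class TestNodeWeakening:
    def test_star_hub_removal_disconnects(self):
        rg = _graph([("hub", f"s{i}", 1.0) for i in range(4)])
        table = node_weakening(rg, ["hub"])
        row = table.table.iloc[0]
        assert row["disconnects"]
        assert row["reachable_fraction"] == 0.0

    def test_path_interior_removal_flagged(self):
        rg = _graph([("A", "B", 1), ("B", "C", 1), ("C", "D", 1)])
        table = node_weakening(rg, ["B"])
        row = table.table[table.table["node"] == "B"].iloc[0]
        assert row["disconnects"]
        # remaining reachable pair is only C-D
        assert row["cpl_without_node"] == pytest.approx(1.0)

    def test_off_path_node_leaves_cpl_unchanged(self):
        # pendant node attached by a very long edge lies on no shortest path
        # between the remaining nodes
        rg = _graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 1.5),
                     ("C", "P", 50.0)])
        table = node_weakening(rg, ["P"])
        row = table.table.iloc[0]
        g_wo = rg.graph.copy()
        g_wo.remove_node("P")
        assert row["cpl_without_node"] == pytest.approx(_brute_force_cpl(g_wo))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_recomputation(self, seed):
        rg = _random_graph(seed + 500)
        nodes = sorted(rg.graph.nodes)
        table = node_weakening(rg, nodes[:3])
        for _, row in table.table.iterrows():
            g_wo = rg.graph.copy()
            g_wo.remove_node(row["node"])
            expected = _brute_force_cpl(g_wo)
            if math.isnan(expected):
                assert math.isnan(row["cpl_without_node"])
            else:
                assert row["cpl_without_node"] == pytest.approx(expected)

    def test_sorted_by_absolute_delta(self):
        rg = _random_graph(4)
        table = node_weakening(rg)
        deltas = table.table["delta_cpl"].abs().to_numpy()
        finite = deltas[~np.isnan(deltas)]
        assert np.all(np.diff(finite) <= 1e-12)
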