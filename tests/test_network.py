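"""pT determination, network construction and hub topology."""

import itertools
import math

import numpy as np
import pytest

from campsn import (
    PersistenceTable,
    auto_pt,
    build_psn,
    compute_pt,
    degree_report,
    delta_degree,
    hydrophobic_cluster_curve,
)


def hydro_table(edges, n_frames=100):
    """PersistenceTable of hydrophobic edges from {(a, b): pct}."""
    return PersistenceTable(
        {((min(a, b), max(a, b)), "hydrophobic"): pct
         for (a, b), pct in edges.items()},
        n_frames,
    )


def largest_component_oracle(edges, nodes):
    """Union-find largest-component size, independent of networkx."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    sizes = {}
    for n in nodes:
        r = find(n)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values()) if sizes else 0


class TestClusterCurve:
    def test_single_edge(self):
        table = hydro_table({("A:L1", "A:L3"): 50.0})
        curve = hydrophobic_cluster_curve(table, [0, 25, 50, 75, 100])
        assert curve == {0: 2, 25: 2, 50: 2, 75: 1, 100: 1}

    def test_fully_persistent_edges_give_constant_curve(self):
        table = hydro_table(
            {("A:L1", "A:L3"): 100.0, ("A:L3", "A:L5"): 100.0}
        )
        curve = hydrophobic_cluster_curve(table, [0, 50, 100])
        assert set(curve.values()) == {3}

    def test_empty_table_gives_zero_curve(self):
        table = PersistenceTable({}, n_frames=10)
        curve = hydrophobic_cluster_curve(table, [0, 50, 100])
        assert set(curve.values()) == {0}

    def test_curve_is_non_increasing(self):
        rng = np.random.default_rng(0)
        nodes = [f"A:L{i}" for i in range(1, 20, 2)]
        edges = {
            pair: float(rng.uniform(0, 100))
            for pair in itertools.combinations(nodes, 2)
            if rng.random() < 0.3
        }
        curve = hydrophobic_cluster_curve(
            hydro_table(edges), list(range(0, 101, 5))
        )
        sizes = [curve[t] for t in sorted(curve)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"A:V{i}" for i in range(1, 25, 2)]
        edges = {
            pair: float(rng.uniform(0, 100))
            for pair in itertools.combinations(nodes, 2)
            if rng.random() < 0.25
        }
        if not edges:
            pytest.skip("no edges drawn")
        table = hydro_table(edges)
        thresholds = sorted(rng.uniform(0, 100, size=8))
        curve = hydrophobic_cluster_curve(table, thresholds)
        touched = {n for pair in edges for n in pair}
        for t in thresholds:
            surviving = [p for p, pct in edges.items() if pct >= t]
            assert curve[t] == largest_component_oracle(surviving, touched)


class TestComputePT:
    def test_single_edge_boundary_is_top_of_scan(self):
        table = hydro_table({("A:L1", "A:L3"): 50.0})
        # max size 2, half-max 1: an isolated node always satisfies the bound
        assert auto_pt(table) == pytest.approx(100.0)

    def test_known_halving_threshold_recovered(self):
        # path of 10 residues: 3 edges at 95%, the bridging edge at 35%, the
        # rest at 5% — the largest cluster (10) halves exactly above 35%
        nodes = [f"A:L{2 * i + 1}" for i in range(10)]
        pcts = [95.0, 95.0, 95.0, 35.0, 5.0, 5.0, 5.0, 5.0, 5.0]
        table = hydro_table(
            {(nodes[i], nodes[i + 1]): pcts[i] for i in range(9)}
        )
        assert auto_pt(table, scan_step=0.1) == pytest.approx(35.0, abs=0.1)

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(3)
        nodes = [f"A:F{2 * i + 1}" for i in range(12)]
        edges = {
            pair: float(rng.uniform(0, 100))
            for pair in itertools.combinations(nodes, 2)
            if rng.random() < 0.2
        }
        table = hydro_table(edges)
        thresholds = [round(0.5 * i, 10) for i in range(201)]
        curve = hydrophobic_cluster_curve(table, thresholds)
        max_size = curve[thresholds[0]]
        half = math.ceil(max_size / 2)
        expected = max(t for t in thresholds if curve[t] >= half)
        assert compute_pt(curve) == pytest.approx(expected)

    def test_threshold_scaling_property(self):
        nodes = [f"A:L{2 * i + 1}" for i in range(10)]
        pcts = [95.0, 95.0, 95.0, 40.0, 5.0, 5.0, 5.0, 5.0, 5.0]
        base = {(nodes[i], nodes[i + 1]): pcts[i] for i in range(9)}
        pt1 = auto_pt(hydro_table(base))
        halved = {k: v / 2.0 for k, v in base.items()}
        pt2 = auto_pt(hydro_table(halved))
        assert pt2 == pytest.approx(pt1 / 2.0, abs=0.1)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError, match="no hydrophobic clusters"):
            compute_pt({0.0: 1, 50.0: 1})
        with pytest.raises(ValueError):
            compute_pt({})


class TestBuildPSN:
    def test_filtering_at_pt(self):
        table = PersistenceTable(
            {(("A:L1", "A:L3"), "hydrophobic"): 30.0,
             (("A:L3", "A:V5"), "hydrophobic"): 20.0},
            100,
        )
        net = build_psn(table, 24.2)
        assert net.graph.number_of_edges() == 1
        assert net.graph.has_edge("A:L1", "A:L3")

    def test_pt_zero_keeps_everything(self):
        table = PersistenceTable(
            {(("A:L1", "A:L3"), "hydrophobic"): 1.0,
             (("A:E2", "A:K6"), "salt_bridge"): 0.5},
            100,
        )
        net = build_psn(table, 0.0)
        assert net.graph.number_of_edges() == 2

    def test_parallel_class_edges_collapse(self):
        table = PersistenceTable(
            {(("A:S1", "A:E5"), "hydrogen_bond"): 80.0,
             (("A:S1", "A:E5"), "salt_bridge"): 60.0},
            100,
        )
        net = build_psn(table, 50.0)
        assert net.graph.number_of_edges() == 1
        assert net.graph.edges["A:S1", "A:E5"]["classes"] == {
            "hydrogen_bond": 80.0, "salt_bridge": 60.0,
        }

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_filter_and_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"A:L{2 * i + 1}" for i in range(10)]
        entries = {}
        for pair in itertools.combinations(nodes, 2):
            for cls in ("hydrophobic", "salt_bridge", "hydrogen_bond"):
                if rng.random() < 0.2:
                    entries[(pair, cls)] = float(rng.uniform(0, 100))
        table = PersistenceTable(entries, 100)
        pt = float(rng.uniform(0, 100))
        net = build_psn(table, pt)
        expected_pairs = {
            tuple(sorted(pair))
            for (pair, _c), pct in entries.items()
            if pct >= pt
        }
        assert {tuple(sorted(e)) for e in net.graph.edges} == expected_pairs

    def test_monotonicity_in_pt(self):
        rng = np.random.default_rng(7)
        nodes = [f"A:M{2 * i + 1}" for i in range(8)]
        entries = {
            (pair, "hydrophobic"): float(rng.uniform(0, 100))
            for pair in itertools.combinations(nodes, 2)
            if rng.random() < 0.5
        }
        table = PersistenceTable(entries, 100)
        prev_edges = None
        for pt in (0.0, 20.0, 40.0, 60.0, 80.0, 100.0):
            net = build_psn(table, pt)
            edges = set(map(frozenset, net.graph.edges))
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges

    def test_degree_sum_is_twice_edge_count(self):
        rng = np.random.default_rng(11)
        nodes = [f"A:I{2 * i + 1}" for i in range(9)]
        entries = {
            (pair, "hydrophobic"): float(rng.uniform(0, 100))
            for pair in itertools.combinations(nodes, 2)
            if rng.random() < 0.4
        }
        net = build_psn(PersistenceTable(entries, 100), 30.0)
        total = sum(d for _, d in net.graph.degree)
        assert total == 2 * net.graph.number_of_edges()


def network_from_pairs(pairs, pt=20.0):
    table = PersistenceTable(
        {(tuple(sorted(p)), "hydrophobic"): 90.0 for p in pairs}, 100
    )
    return build_psn(table, pt)


class TestDegreeAndDeltaDegree:
    def test_triangle_has_no_hubs(self):
        net = network_from_pairs(
            [("A:L1", "A:L3"), ("A:L3", "A:L5"), ("A:L1", "A:L5")]
        )
        report = degree_report(net)
        assert set(report.degrees.values()) == {2}
        assert report.hubs == []

    def test_star_center_reaches_maximum_degree(self):
        center = "A:L1"
        leaves = [f"A:V{2 * i + 1}" for i in range(1, 9)]
        net = network_from_pairs([(center, leaf) for leaf in leaves])
        report = degree_report(net)
        assert report.degree(center) == 8
        assert report.hubs == [center]
        assert report.high_hubs == [center]

    @pytest.mark.parametrize("seed", range(3))
    def test_degrees_match_neighbor_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"A:A{2 * i + 1}" for i in range(12)]
        pairs = [
            p for p in itertools.combinations(nodes, 2) if rng.random() < 0.3
        ]
        if not pairs:
            pytest.skip("no edges drawn")
        net = network_from_pairs(pairs)
        report = degree_report(net)
        for node in net.nodes:
            expected = sum(node in p for p in pairs)
            assert report.degree(node) == expected

    def test_identical_networks_have_zero_delta(self):
        net = network_from_pairs([("A:L1", "A:L3"), ("A:L3", "A:L5")])
        rep = degree_report(net)
        df = delta_degree(rep, rep)
        assert (df["delta_degree"] == 0).all()

    def test_hub_collapse_gives_negative_delta(self):
        center = "A:D129"
        leaves = [f"A:L{2 * i + 1}" for i in range(1, 9)]
        ref = degree_report(
            network_from_pairs([(center, leaf) for leaf in leaves])
        )
        var = degree_report(
            network_from_pairs([(center, leaf) for leaf in leaves[:2]])
        )
        df = delta_degree(var, ref)
        assert df.loc[df["node"] == center, "delta_degree"].iloc[0] == -6

    def test_high_hub_restriction(self):
        center = "A:D129"
        leaves = [f"A:L{2 * i + 1}" for i in range(1, 9)]
        ref = degree_report(
            network_from_pairs([(center, leaf) for leaf in leaves])
        )
        var = degree_report(
            network_from_pairs([(center, leaf) for leaf in leaves[:2]])
        )
        df = delta_degree(var, ref, restrict_high_hubs=True)
        # only the center is a high hub in either network
        assert list(df["node"]) == [center]

    def test_disjoint_node_sets_rejected(self):
        a = degree_report(network_from_pairs([("A:L1", "A:L3")]))
        b = degree_report(network_from_pairs([("B:V1", "B:V3")]))
        with pytest.raises(ValueError):
            delta_degree(a, b)

    @pytest.mark.parametrize("seed", range(3))
    def test_delta_matches_subtraction_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        nodes = [f"A:L{2 * i + 1}" for i in range(10)]
        pairs_a = [
            p for p in itertools.combinations(nodes, 2) if rng.random() < 0.3
        ]
        pairs_b = [
            p for p in itertools.combinations(nodes, 2) if rng.random() < 0.3
        ]
        if not pairs_a or not pairs_b:
            pytest.skip("empty graph drawn")
        rep_a = degree_report(network_from_pairs(pairs_a))
        rep_b = degree_report(network_from_pairs(pairs_b))
        df = delta_degree(rep_a, rep_b)
        for _, row in df.iterrows():
            n = row["node"]
            assert row["delta_degree"] == (
                sum(n in p for p in pairs_a) - sum(n in p for p in pairs_b)
            )
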