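"""Persistence-filtered protein structure networks (PSN).

The persistence threshold pT is chosen by the half-maximal hydrophobic
cluster criterion: scan thresholds t, keep hydrophobic edges with
persistence ≥ t, and record the node count of the largest connected
component. pT is the largest scanned threshold at which that size is still
at least half (``ceil(max/2)``) of its value at the lowest threshold. The
full network then keeps edges of every interaction class with
persistence ≥ pT; parallel class edges between the same residue pair
collapse to a single adjacency (class annotations retained) for degree and
shortest-path purposes.

Hubs are residues of degree ≥ 4, high-degree hubs ≥ 6; ΔDegree compares a
variant network against a reference (e.g. wild type) per node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .interactions import PersistenceTable

__all__ = [
    "StructureNetwork",
    "HubReport",
    "hydrophobic_cluster_curve",
    "compute_pt",
    "auto_pt",
    "build_psn",
    "degree_report",
    "delta_degree",
]


# ---------------------------------------------------------------------------
# pT determination
# ---------------------------------------------------------------------------


def hydrophobic_cluster_curve(
    table: PersistenceTable, thresholds: Sequence[float]
) -> dict[float, int]:
    """Largest hydrophobic-cluster size (node count) per persistence threshold.

    Every residue occurring in a hydrophobic entry stays a node at all
    thresholds, so the size floor is 1 (an isolated residue) once any
    hydrophobic pair was ever recorded; an empty table gives all zeros.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    if any(t < 0 or t > 100 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 100]")
    hydro = table.subset("hydrophobic")
    nodes = {r for pair in hydro for r in pair}
    curve: dict[float, int] = {}
    for t in thresholds:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(pair for pair, pct in hydro.items() if pct >= t)
        if g.number_of_nodes() == 0:
            curve[t] = 0
        else:
            curve[t] = max(len(c) for c in nx.connected_components(g))
    return curve


def compute_pt(curve: Mapping[float, int]) -> float:
    """Half-maximal crossing of a hydrophobic cluster-size curve.

    Returns the largest scanned threshold at which the largest-cluster size
    is still ≥ ceil(max/2), where max is the size at the lowest scanned
    threshold. Ties resolve toward the larger (stricter) threshold.
    """
    if not curve:
        raise ValueError("empty cluster-size curve")
    thresholds = sorted(curve)
    max_size = curve[thresholds[0]]
    if max_size <= 1:
        raise ValueError(
            "no hydrophobic clusters: largest cluster size "
            f"{max_size} at the lowest threshold"
        )
    half = math.ceil(max_size / 2)
    qualifying = [t for t in thresholds if curve[t] >= half]
    return float(max(qualifying))


def auto_pt(
    table: PersistenceTable, scan_step: float = 0.1, scan_max: float = 100.0
) -> float:
    """Scan thresholds 0..scan_max at ``scan_step`` and apply :func:`compute_pt`."""
    n = int(round(scan_max / scan_step))
    thresholds = [round(i * scan_step, 10) for i in range(n + 1)]
    return compute_pt(hydrophobic_cluster_curve(table, thresholds))


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


@dataclass
class StructureNetwork:
    """Undirected residue graph filtered at persistence threshold pT (%).

    ``graph`` nodes are residue labels ``chain:X<resid>``; each edge carries
    a ``classes`` dict mapping interaction class → persistence %.
    """

    graph: nx.Graph
    pt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pt <= 100.0:
            raise ValueError("pT must lie in [0, 100]")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-edges are not allowed")
            if any(p < self.pt for p in data.get("classes", {}).values()):
                raise ValueError(f"edge {u}-{v} below pT")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def resolve(self, token: str) -> str | None:
        """Resolve a residue token to a node label.

        Accepts full labels (``A:E31``), chain-less one-letter+index tokens
        (``E31``), or bare indices (``31``). Chain-less tokens match the
        first chain (alphabetically) containing the residue.
        """
        if token in self.graph:
            return token
        candidates = sorted(
            n for n in self.graph.nodes if n.split(":", 1)[1] == token
        )
        if candidates:
            return candidates[0]
        # bare index: match any residue number
        if token.isdigit():
            candidates = sorted(
                n for n in self.graph.nodes
                if n.split(":", 1)[1][1:] == token
            )
            if candidates:
                return candidates[0]
        return None

    # -- export ------------------------------------------------------------

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        g.graph["pT"] = self.pt
        g.add_nodes_from(self.graph.nodes)
        for u, v, data in self.graph.edges(data=True):
            classes = data.get("classes", {})
            g.add_edge(
                u, v,
                classes=";".join(
                    f"{c}={p:.6g}" for c, p in sorted(classes.items())
                ),
            )
        nx.write_graphml(g, str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "StructureNetwork":
        g = nx.read_graphml(str(path))
        out = nx.Graph()
        out.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            classes = {}
            for item in str(data.get("classes", "")).split(";"):
                if "=" in item:
                    c, p = item.split("=")
                    classes[c] = float(p)
            out.add_edge(u, v, classes=classes)
        return cls(out, float(g.graph["pT"]))

    def to_edgelist(self) -> pd.DataFrame:
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            for cls, pct in sorted(data.get("classes", {}).items()):
                rows.append((u, v, cls, pct))
        return pd.DataFrame(
            rows, columns=["res_a", "res_b", "class", "persistence_pct"]
        )


def build_psn(table: PersistenceTable, pt: float) -> StructureNetwork:
    """Filter a persistence table at pT and build the residue network.

    Edges of all interaction classes with persistence ≥ pT are kept; every
    residue named in the table remains a node even if all its interactions
    fall below pT.
    """
    if not 0.0 <= pt <= 100.0:
        raise ValueError("pT must lie in [0, 100]")
    g = nx.Graph()
    for (pair, _cls) in table.entries:
        g.add_nodes_from(pair)
    for (pair, cls), pct in table.entries.items():
        if pct >= pt:
            if g.has_edge(*pair):
                g.edges[pair]["classes"][cls] = pct
            else:
                g.add_edge(*pair, classes={cls: pct})
    return StructureNetwork(g, pt)


# ---------------------------------------------------------------------------
# Degrees, hubs, ΔDegree
# ---------------------------------------------------------------------------


@dataclass
class HubReport:
    """Per-residue degree with hub flags, sorted by descending degree."""

    table: pd.DataFrame
    hub_min: int
    high_hub_min: int

    def degree(self, node: str) -> int:
        row = self.table.loc[self.table["node"] == node, "degree"]
        if row.empty:
            raise KeyError(node)
        return int(row.iloc[0])

    @property
    def degrees(self) -> dict[str, int]:
        return dict(zip(self.table["node"], self.table["degree"]))

    @property
    def hubs(self) -> list[str]:
        return list(self.table.loc[self.table["is_hub"], "node"])

    @property
    def high_hubs(self) -> list[str]:
        return list(self.table.loc[self.table["is_high_hub"], "node"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def degree_report(
    network: StructureNetwork, hub_min: int = 4, high_hub_min: int = 6
) -> HubReport:
    """Degree centrality (number of incident edges) and hub classification."""
    rows = [
        {
            "node": n,
            "degree": int(d),
            "is_hub": d >= hub_min,
            "is_high_hub": d >= high_hub_min,
        }
        for n, d in network.graph.degree
    ]
    df = pd.DataFrame(
        rows, columns=["node", "degree", "is_hub", "is_high_hub"]
    ).sort_values(["degree", "node"], ascending=[False, True])
    return HubReport(df.reset_index(drop=True), hub_min, high_hub_min)


def delta_degree(
    variant: HubReport,
    reference: HubReport,
    restrict_high_hubs: bool = False,
) -> pd.DataFrame:
    """ΔDegree(node) = degree_variant − degree_reference over shared nodes.

    With ``restrict_high_hubs`` only residues meeting the high-hub criterion
    in at least one of the two networks are reported.
    """
    dv, dr = variant.degrees, reference.degrees
    shared = sorted(set(dv) & set(dr))
    if not shared:
        raise ValueError("variant and reference share no nodes")
    rows = []
    for n in shared:
        if restrict_high_hubs and not (
            dv[n] >= variant.high_hub_min or dr[n] >= reference.high_hub_min
        ):
            continue
        rows.append(
            {
                "node": n,
                "degree_variant": dv[n],
                "degree_reference": dr[n],
                "delta_degree": dv[n] - dr[n],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["node", "degree_variant", "degree_reference", "delta_degree"],
    )
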