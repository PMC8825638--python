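"""Communication Robustness (CR) between residues of a structure network.

CR(A,B) = nAB · pT / l, where nAB is the number of distinct unweighted
shortest paths between residues A and B, l their hop length, and pT the
persistence threshold of the network expressed as a fraction of 1 (a pT of
24.2% enters as 0.242, keeping CR in the O(0.1–0.5) range used to classify
"robust" communication). Disconnected pairs score 0.

The default query maps the communication among the four EF-hand bidentate
Ca²⁺-coordinating glutamates of calmodulin (E31, E67, E104, E140) and from
each EF-hand to the residues of the target-binding interface.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .network import StructureNetwork

__all__ = [
    "DEFAULT_EF_HAND_SOURCES",
    "DEFAULT_INTERFACE_TARGETS",
    "CommunicationQuery",
    "CRMatrix",
    "shortest_path_census",
    "communication_robustness",
    "communication_map",
]

#: bidentate Ca²⁺-coordinating Glu of EF-hands 1–4 (mature-protein numbering)
DEFAULT_EF_HAND_SOURCES = ("E31", "E67", "E104", "E140")

#: interface residues persistently contacting the target peptide in the
#: wild-type complex. Position 15 appears under both identities ("E15" and
#: "A15"); both tokens are accepted and whichever resolves is used.
DEFAULT_INTERFACE_TARGETS = (
    "E11", "E15", "A15", "F19", "E47", "M72", "K75", "E84", "A88",
    "L112", "E114", "E120", "E123", "M124", "E127", "A128", "M144", "M145",
)


@dataclass
class CommunicationQuery:
    """Source and target residue tokens for a CR map."""

    sources: Sequence[str] = DEFAULT_EF_HAND_SOURCES
    targets: Sequence[str] = DEFAULT_INTERFACE_TARGETS

    def __post_init__(self) -> None:
        # dedupe preserving order
        self.sources = list(dict.fromkeys(self.sources))
        self.targets = list(dict.fromkeys(self.targets))
        if not self.sources or not self.targets:
            raise ValueError("sources and targets must be non-empty")


def shortest_path_census(
    network: StructureNetwork, a: str, b: str
) -> tuple[int, float]:
    """Count shortest paths between two residues.

    Returns ``(nAB, l)`` where l is the unweighted shortest-path length in
    edges and nAB the number of distinct geodesics of that length, counted
    by dynamic programming over BFS layers. Disconnected pairs return
    ``(0, inf)``.
    """
    g = network.graph
    if a == b:
        raise ValueError("source and target must differ")
    for node in (a, b):
        if node not in g:
            raise KeyError(f"residue {node!r} not in network")
    dist = {a: 0}
    count = {a: 1}
    queue = deque([a])
    while queue:
        u = queue.popleft()
        if u == b:
            break
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                count[v] = count[u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                count[v] += count[u]
    if b not in dist:
        return 0, math.inf
    return count[b], float(dist[b])


def communication_robustness(
    network: StructureNetwork,
    a: str,
    b: str,
    pt_as_fraction: bool = True,
) -> dict:
    """CR(A,B) = nAB·pT/l with pT as a fraction of 1 (switchable)."""
    n_ab, length = shortest_path_census(network, a, b)
    pt = network.pt / 100.0 if pt_as_fraction else network.pt
    cr = 0.0 if n_ab == 0 else n_ab * pt / length
    return {
        "source": a,
        "target": b,
        "nAB": n_ab,
        "l": length,
        "pT": network.pt,
        "CR": cr,
    }


@dataclass
class CRMatrix:
    """Long-form CR results plus the EF-hand (source↔source) sub-map."""

    table: pd.DataFrame
    source_pairs: pd.DataFrame
    unresolved: list[str] = field(default_factory=list)

    def matrix(self) -> pd.DataFrame:
        """Sources × targets pivot of CR values."""
        return self.table.pivot(index="source", columns="target", values="CR")

    def mean_cr_per_source(self) -> pd.Series:
        return self.table.groupby("source")["CR"].mean()

    def to_csv(self, path: str | Path) -> None:
        pd.concat([self.table, self.source_pairs]).to_csv(path, index=False)

    def source_matrix(self) -> pd.DataFrame:
        """Symmetric source×source CR matrix (diagonal zero)."""
        sources = sorted(
            set(self.source_pairs["source"]) | set(self.source_pairs["target"])
        )
        m = pd.DataFrame(0.0, index=sources, columns=sources)
        for _, row in self.source_pairs.iterrows():
            m.loc[row["source"], row["target"]] = row["CR"]
            m.loc[row["target"], row["source"]] = row["CR"]
        return m


def communication_map(
    network: StructureNetwork,
    query: CommunicationQuery | None = None,
    pt_as_fraction: bool = True,
) -> CRMatrix:
    """CR over all source×target pairs plus all source–source pairs.

    Tokens that do not resolve in the network are reported in
    ``unresolved`` with a warning; the map is computed on the rest.
    """
    query = query or CommunicationQuery()
    unresolved: list[str] = []

    def _resolve(tokens: Sequence[str]) -> list[str]:
        out = []
        for tok in tokens:
            node = network.resolve(tok)
            if node is None:
                unresolved.append(tok)
            elif node not in out:
                out.append(node)
        return out

    sources = _resolve(query.sources)
    targets = _resolve(query.targets)
    if unresolved:
        warnings.warn(
            f"unresolvable residue tokens skipped: {unresolved}",
            stacklevel=2,
        )
    if not sources or not targets:
        raise ValueError("no resolvable sources or targets")
    rows = [
        communication_robustness(network, s, t, pt_as_fraction)
        for s in sources
        for t in targets
        if s != t
    ]
    pair_rows = [
        communication_robustness(network, a, b, pt_as_fraction)
        for i, a in enumerate(sources)
        for b in sources[i + 1:]
    ]
    cols = ["source", "target", "nAB", "l", "pT", "CR"]
    return CRMatrix(
        table=pd.DataFrame(rows, columns=cols),
        source_pairs=pd.DataFrame(pair_rows, columns=cols),
        unresolved=unresolved,
    )
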