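"""Per-state networks from coefficient tensors; differential edges and hubs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import TreeglError
from .solver import CoefficientTensor

__all__ = [
    "GeneNetwork",
    "DifferentialSet",
    "symmetrize_max",
    "filter_edges",
    "shared_and_differential",
    "hubs",
    "hub_neighborhood",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise TreeglError(f"self loop on gene {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class GeneNetwork:
    """Weighted undirected network for one state.

    Edges are keyed by canonical gene pair (lexicographic order) and every
    stored weight is nonzero.
    """

    state: str
    genes: tuple[str, ...]
    edges: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        universe = set(self.genes)
        canon: dict[tuple[str, str], float] = {}
        for (a, b), w in self.edges.items():
            pair = canonical_pair(a, b)
            if pair[0] not in universe or pair[1] not in universe:
                raise TreeglError(f"edge {pair} outside gene universe")
            if pair in canon and canon[pair] != w:
                raise TreeglError(f"conflicting weights for edge {pair}")
            if w == 0:
                raise TreeglError(f"zero-weight edge {pair} not allowed")
            canon[pair] = float(w)
        self.edges = canon

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, positive_only: bool = False) -> dict[str, int]:
        deg = {g: 0 for g in self.genes}
        for (a, b), w in self.edges.items():
            if positive_only and w <= 0:
                continue
            deg[a] += 1
            deg[b] += 1
        return deg

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.genes:
            raise TreeglError(f"gene {gene!r} not in network universe")
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out


@dataclass
class DifferentialSet:
    """Shared edges plus per-state state-specific (differential) edge sets."""

    shared: set[tuple[str, str]]
    differential: dict[str, set[tuple[str, str]]]

    def __post_init__(self) -> None:
        states = list(self.differential)
        for i, s in enumerate(states):
            if self.shared & self.differential[s]:
                raise TreeglError("shared and differential sets must be disjoint")
            for t in states[i + 1:]:
                if self.differential[s] & self.differential[t]:
                    raise TreeglError("differential sets must be pairwise disjoint")


def symmetrize_max(tensor: CoefficientTensor) -> list[GeneNetwork]:
    """One network per state: edge (i,j) present iff either B[i,j] or B[j,i]
    is nonzero; the weight is whichever coefficient has larger magnitude
    (ties broken toward B[i,j] with i<j in canonical gene order)."""
    nets = []
    genes = tensor.genes
    for state in tensor.states:
        B = tensor.coef[state]
        edges: dict[tuple[str, str], float] = {}
        ii, jj = np.nonzero(np.triu(np.abs(B) + np.abs(B.T), 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            wij, wji = B[i, j], B[j, i]
            w = wij if abs(wij) >= abs(wji) else wji
            gi, gj = genes[i], genes[j]
            edges[canonical_pair(gi, gj)] = w
        nets.append(GeneNetwork(state=state, genes=genes, edges=edges))
    return nets


def filter_edges(net: GeneNetwork, mode: str, threshold: float = 0.0) -> GeneNetwork:
    """Keep edges with |w| > threshold (``abs_threshold``) or w > 0
    (``positive_only``)."""
    if threshold < 0:
        raise TreeglError("threshold must be non-negative")
    if mode == "abs_threshold":
        kept = {p: w for p, w in net.edges.items() if abs(w) > threshold}
    elif mode == "positive_only":
        kept = {p: w for p, w in net.edges.items() if w > 0}
    else:
        raise TreeglError(f"unknown filter mode {mode!r}")
    return GeneNetwork(state=net.state, genes=net.genes, edges=kept)


def shared_and_differential(nets: list[GeneNetwork]) -> DifferentialSet:
    """Edges present in every network, and per-state edges present nowhere else.

    Presence only — weights are ignored.
    """
    if len(nets) < 2:
        raise TreeglError("need at least 2 networks")
    universe = nets[0].genes
    for net in nets[1:]:
        if net.genes != universe:
            raise TreeglError("networks must share one gene universe")
    edge_sets = {net.state: set(net.edges) for net in nets}
    if len(edge_sets) != len(nets):
        raise TreeglError("duplicate state among networks")
    shared = set.intersection(*edge_sets.values())
    differential = {}
    for state, edges in edge_sets.items():
        others = set.union(*(e for s, e in edge_sets.items() if s != state))
        differential[state] = edges - others
    return DifferentialSet(shared=shared, differential=differential)


def hubs(
    net: GeneNetwork, degree_threshold: int = 5, positive_only: bool = True
) -> list[tuple[str, int]]:
    """Genes with degree strictly greater than the threshold, sorted by
    descending degree then gene id.  Degree counts positive-weight edges only
    when ``positive_only`` is set."""
    if degree_threshold < 0:
        raise TreeglError("degree threshold must be non-negative")
    deg = net.degree(positive_only=positive_only)
    out = [(g, d) for g, d in deg.items() if d > degree_threshold]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def hub_neighborhood(net: GeneNetwork, gene: str) -> GeneNetwork:
    """Induced subnetwork on a gene and its direct neighbors (including
    neighbor-neighbor edges)."""
    members = net.neighbors(gene) | {gene}
    kept = {
        pair: w for pair, w in net.edges.items() if pair[0] in members and pair[1] in members
    }
    sub_genes = tuple(g for g in net.genes if g in members)
    return GeneNetwork(state=net.state, genes=sub_genes, edges=kept)
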