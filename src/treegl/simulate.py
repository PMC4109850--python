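"""Synthetic tree-related network collections and Gaussian expression samples.

A root graph with mean degree 4 and maximum degree 6 branches twice into a
depth-3 binary tree of seven distinct networks (A; B,C; D,E,F,G).  At each
branching a fixed fraction (default 25%) of the parent's edges is deleted and
replaced by the same number of fresh edges.  Every distinct network holds for
one contiguous segment of states, and i.i.d. multivariate-Gaussian samples are
drawn per state from a precision matrix whose support matches the adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import ExpressionPanel, StateTree, TreeglError, write_panel, write_tree

__all__ = [
    "TrueNetworkCollection",
    "generate_root_network",
    "rewire_child",
    "build_tree_collection",
    "adjacency_to_precision",
    "sample_panel",
]

MAX_DEGREE = 6
MEAN_DEGREE = 4
BRANCH_FRACTION = 0.25

# distinct-network labels in segment order: root, its two children, then the
# four grandchildren (depth-first by parent)
NETWORK_LABELS = ("A", "B", "C", "D", "E", "F", "G")
NETWORK_PARENTS = {"A": None, "B": "A", "C": "A", "D": "B", "E": "B", "F": "C", "G": "C"}


@dataclass
class TrueNetworkCollection:
    """Ground truth for a simulation run.

    ``distinct_networks`` are boolean adjacency matrices, ``precisions`` the
    matching SPD precision matrices, and ``state_map`` sends each state id to
    the index of its distinct network.  States mapped to one network form a
    contiguous segment of ``tree``.
    """

    distinct_networks: list[np.ndarray]
    precisions: list[np.ndarray]
    state_map: dict[str, int]
    tree: StateTree
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.distinct_networks) != len(self.precisions):
            raise TreeglError("adjacency/precision count mismatch")
        for adj, prec in zip(self.distinct_networks, self.precisions):
            _check_adjacency(adj)
            if not np.allclose(prec, prec.T):
                raise TreeglError("precision matrix not symmetric")
            if np.linalg.eigvalsh(prec)[0] <= 0:
                raise TreeglError("precision matrix not positive definite")
            off = prec.copy()
            np.fill_diagonal(off, 0.0)
            if not np.array_equal(off != 0, adj):
                raise TreeglError("precision support does not match adjacency")
        if set(self.state_map) != set(self.tree.states):
            raise TreeglError("state map must cover exactly the tree states")

    @property
    def n_states(self) -> int:
        return len(self.state_map)

    def adjacency_for_state(self, state: str) -> np.ndarray:
        return self.distinct_networks[self.state_map[state]]

    def precision_for_state(self, state: str) -> np.ndarray:
        return self.precisions[self.state_map[state]]


def _check_adjacency(adj: np.ndarray) -> None:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise TreeglError("adjacency must be square")
    if adj.dtype != bool:
        raise TreeglError("adjacency must be boolean")
    if not np.array_equal(adj, adj.T):
        raise TreeglError("adjacency must be symmetric")
    if np.any(np.diag(adj)):
        raise TreeglError("adjacency must have an empty diagonal")


def _edge_set(adj: np.ndarray) -> set[tuple[int, int]]:
    ii, jj = np.nonzero(np.triu(adj, 1))
    return set(zip(ii.tolist(), jj.tolist()))


def _adj_from_edges(p: int, edges) -> np.ndarray:
    adj = np.zeros((p, p), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return adj


def generate_root_network(p: int, seed) -> np.ndarray:
    """Random graph on ``p`` nodes with exactly ``2p`` edges, max degree 6.

    Uniform rejection sampler: repeatedly draw a uniformly random non-edge
    whose endpoints both have degree < 6; restart from scratch if the sampler
    stalls (10*p^2 failed draws).
    """
    if p < 4:
        raise TreeglError("need at least 4 nodes")
    n_edges = MEAN_DEGREE * p // 2
    if n_edges > p * (p - 1) // 2 or 2 * n_edges > MAX_DEGREE * p:
        raise TreeglError(f"cannot host {n_edges} edges on {p} nodes under the degree cap")
    rng = np.random.default_rng(seed)
    max_fail = 10 * p * p
    while True:  # full restarts are rare; each attempt almost always completes
        degree = np.zeros(p, dtype=int)
        edges: set[tuple[int, int]] = set()
        fails = 0
        while len(edges) < n_edges and fails < max_fail:
            i, j = rng.integers(0, p, size=2)
            if i == j:
                continue
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in edges or degree[a] >= MAX_DEGREE or degree[b] >= MAX_DEGREE:
                fails += 1
                continue
            edges.add((a, b))
            degree[a] += 1
            degree[b] += 1
        if len(edges) == n_edges:
            return _adj_from_edges(p, edges)


def rewire_child(parent_adj: np.ndarray, fraction: float, seed) -> np.ndarray:
    """Delete round(fraction*E) random parent edges and add as many new ones.

    New edges are drawn uniformly among the parent's non-edges (so deleted
    edges are never restored) subject to the degree cap on the child.
    """
    _check_adjacency(parent_adj)
    if not (0.0 <= fraction <= 1.0):
        raise TreeglError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = parent_adj.shape[0]
    parent_edges = sorted(_edge_set(parent_adj))
    n_edges = len(parent_edges)
    k = round(fraction * n_edges)  # round-half-to-even
    if k == 0:
        return parent_adj.copy()

    candidates = sorted(
        {(i, j) for i in range(p) for j in range(i + 1, p)} - set(parent_edges)
    )
    for _attempt in range(100):
        drop_idx = rng.choice(n_edges, size=k, replace=False)
        kept = [e for i, e in enumerate(parent_edges) if i not in set(drop_idx.tolist())]
        degree = np.zeros(p, dtype=int)
        for i, j in kept:
            degree[i] += 1
            degree[j] += 1
        order = rng.permutation(len(candidates))
        added: list[tuple[int, int]] = []
        for idx in order:
            if len(added) == k:
                break
            i, j = candidates[idx]
            if degree[i] < MAX_DEGREE and degree[j] < MAX_DEGREE:
                added.append((i, j))
                degree[i] += 1
                degree[j] += 1
        if len(added) == k:
            return _adj_from_edges(p, kept + added)
    raise TreeglError(
        f"could not place {k} replacement edges under the degree-{MAX_DEGREE} cap "
        f"after 100 attempts (p={p}, E={n_edges})"
    )


def adjacency_to_precision(
    adj: np.ndarray, weight_low: float = 0.2, weight_high: float = 0.4, seed=None
) -> np.ndarray:
    """SPD precision matrix with off-diagonal support exactly ``adj``.

    Edge magnitudes are uniform in [weight_low, weight_high] with random sign;
    each diagonal entry is the absolute row sum plus 0.1, which makes the
    matrix strictly diagonally dominant and hence positive definite.
    """
    _check_adjacency(adj)
    if not (0 < weight_low <= weight_high):
        raise TreeglError("need 0 < weight_low <= weight_high")
    rng = np.random.default_rng(seed)
    p = adj.shape[0]
    omega = np.zeros((p, p))
    for i, j in sorted(_edge_set(adj)):
        w = rng.uniform(weight_low, weight_high) * rng.choice([-1.0, 1.0])
        omega[i, j] = omega[j, i] = w
    np.fill_diagonal(omega, np.sum(np.abs(omega), axis=1) + 0.1)
    return omega


def build_tree_collection(
    p: int,
    segment_len: int,
    seed,
    fraction: float = BRANCH_FRACTION,
    weight_low: float = 0.2,
    weight_high: float = 0.4,
) -> TrueNetworkCollection:
    """Seven distinct networks on a chain-of-segments state tree.

    Distinct network A is the root; B and C rewire A; D,E rewire B and F,G
    rewire C.  Each network holds for ``segment_len`` consecutive states; the
    head of a child segment attaches to the last state of its parent segment.
    State numbering follows segment order A, B, C, D, E, F, G.
    """
    if segment_len < 1:
        raise TreeglError("segment_len must be at least 1")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    keys = ("rootA", "rewB", "rewC", "rewD", "rewE", "rewF", "rewG",
            "precA", "precB", "precC", "precD", "precE", "precF", "precG")
    child_seeds = dict(zip(keys, ss.spawn(len(keys))))

    adjs: dict[str, np.ndarray] = {"A": generate_root_network(p, child_seeds["rootA"])}
    for label in NETWORK_LABELS[1:]:
        adjs[label] = rewire_child(
            adjs[NETWORK_PARENTS[label]], fraction, child_seeds[f"rew{label}"]
        )
    precisions = [
        adjacency_to_precision(adjs[l], weight_low, weight_high, child_seeds[f"prec{l}"])
        for l in NETWORK_LABELS
    ]

    states: list[str] = []
    parent: dict[str, str | None] = {}
    state_map: dict[str, int] = {}
    seg_last: dict[str, str] = {}
    counter = 0
    for net_idx, label in enumerate(NETWORK_LABELS):
        for k in range(segment_len):
            counter += 1
            sid = f"s{counter}"
            states.append(sid)
            state_map[sid] = net_idx
            if k > 0:
                parent[sid] = states[-2]
            elif NETWORK_PARENTS[label] is None:
                parent[sid] = None
            else:
                parent[sid] = seg_last[NETWORK_PARENTS[label]]
        seg_last[label] = states[-1]

    tree = StateTree(tuple(states), parent, anchor_pairs=())
    genes = tuple(f"g{i + 1}" for i in range(p))
    return TrueNetworkCollection(
        distinct_networks=[adjs[l] for l in NETWORK_LABELS],
        precisions=precisions,
        state_map=state_map,
        tree=tree,
        genes=genes,
    )


def sample_panel(
    collection: TrueNetworkCollection, n_per_state: int, seed
) -> ExpressionPanel:
    """Draw ``n_per_state`` zero-mean Gaussian samples per state.

    Each state's covariance is the inverse of its network's precision matrix;
    draws use the Cholesky factor of the precision so results are reproducible
    given the seed.
    """
    if n_per_state < 1:
        raise TreeglError("n_per_state must be at least 1")
    rng = np.random.default_rng(seed)
    blocks: dict[str, np.ndarray] = {}
    sample_ids: dict[str, tuple[str, ...]] = {}
    chol_cache: dict[int, np.ndarray] = {}
    p = len(collection.genes)
    for state in collection.tree.states:
        idx = collection.state_map[state]
        if idx not in chol_cache:
            chol_cache[idx] = np.linalg.cholesky(collection.precisions[idx])
        L = chol_cache[idx]
        z = rng.standard_normal((n_per_state, p))
        # x = L^{-T} z has covariance (L L^T)^{-1} = Omega^{-1}
        from scipy.linalg import solve_triangular

        blocks[state] = solve_triangular(L.T, z.T, lower=False).T
        sample_ids[state] = tuple(f"{state}_r{i + 1}" for i in range(n_per_state))
    return ExpressionPanel(genes=collection.genes, blocks=blocks, sample_ids=sample_ids)


def write_collection(collection: TrueNetworkCollection, out_dir: str | Path) -> None:
    """Write tree, truth edge lists and state map for a simulated collection."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tree(collection.tree, out / "tree.tsv")
    with open(out / "truth_edges.tsv", "w") as fh:
        fh.write("network\tgene_i\tgene_j\tprecision\n")
        for label, adj, prec in zip(
            NETWORK_LABELS, collection.distinct_networks, collection.precisions
        ):
            for i, j in sorted(_edge_set(adj)):
                gi, gj = collection.genes[i], collection.genes[j]
                fh.write(f"{label}\t{gi}\t{gj}\t{prec[i, j]:.17g}\n")
    with open(out / "truth_states.tsv", "w") as fh:
        fh.write("state\tnetwork\n")
        for state in collection.tree.states:
            fh.write(f"{state}\t{NETWORK_LABELS[collection.state_map[state]]}\n")


def simulate_to_dir(
    p: int, n_per_state: int, segment_len: int, seed, out_dir: str | Path
) -> tuple[TrueNetworkCollection, ExpressionPanel]:
    """Full simulation: collection + panel, written to ``out_dir`` with metadata."""
    import json

    ss = np.random.SeedSequence(seed)
    coll_seed, panel_seed = ss.spawn(2)
    collection = build_tree_collection(p, segment_len, coll_seed)
    panel = sample_panel(collection, n_per_state, panel_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_collection(collection, out)
    write_panel(panel, out / "panel.tsv", out / "samples.tsv")
    (out / "meta.json").write_text(
        json.dumps(
            {"nodes": p, "samples": n_per_state, "segment_len": segment_len, "seed": seed},
            indent=2,
        )
    )
    return collection, panel
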