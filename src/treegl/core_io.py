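"""Domain types, file formats and configuration shared by all pipeline stages.

File formats are deliberately plain: tab-separated text with headers, so that
panels, trees and edge lists survive version control and diffing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("treegl")

__all__ = [
    "StateTree",
    "ExpressionPanel",
    "AnalysisConfig",
    "read_panel",
    "write_panel",
    "read_tree",
    "write_tree",
    "write_networks",
    "read_networks",
]


class TreeglError(ValueError):
    """Raised on invalid inputs anywhere in the pipeline."""


# ---------------------------------------------------------------------------
# StateTree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateTree:
    """Cell states related by parent pointers, plus anchor fusion pairs.

    ``parent`` maps every state to its parent; exactly one state (the root)
    maps to ``None``.  ``anchor_pairs`` lists (state, ancestor) pairs that
    receive an extra fusion penalty on top of the child-parent ones.
    """

    states: tuple[str, ...]
    parent: Mapping[str, str | None]
    anchor_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "parent", dict(self.parent))
        object.__setattr__(
            self, "anchor_pairs", tuple((a, b) for a, b in self.anchor_pairs)
        )
        self._validate()

    def _validate(self) -> None:
        if len(self.states) == 0:
            raise TreeglError("state tree must contain at least one state")
        if any(not s for s in self.states):
            raise TreeglError("state identifiers must be non-empty")
        if len(set(self.states)) != len(self.states):
            raise TreeglError("state identifiers must be unique")
        sset = set(self.states)
        if set(self.parent) != sset:
            raise TreeglError("parent map must cover exactly the states")
        roots = [s for s in self.states if self.parent[s] is None]
        if len(roots) != 1:
            raise TreeglError(f"expected exactly one root, found {len(roots)}")
        for s, p in self.parent.items():
            if p is not None and p not in sset:
                raise TreeglError(f"parent {p!r} of state {s!r} is not a state")
        # acyclicity: walking up from every state must terminate at the root
        for s in self.states:
            seen = set()
            cur: str | None = s
            while cur is not None:
                if cur in seen:
                    raise TreeglError(f"cycle in parent map involving {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]
        for s, a in self.anchor_pairs:
            if s not in sset or a not in sset:
                raise TreeglError(f"anchor pair ({s!r}, {a!r}) references unknown state")
            if a not in self._ancestors(s):
                raise TreeglError(
                    f"anchor {a!r} is not a strict ancestor of state {s!r}"
                )

    def _ancestors(self, state: str) -> set[str]:
        out: set[str] = set()
        cur = self.parent[state]
        while cur is not None:
            out.add(cur)
            cur = self.parent[cur]
        return out

    @property
    def root(self) -> str:
        return next(s for s in self.states if self.parent[s] is None)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """(child, parent) pairs in state order."""
        return tuple(
            (s, p) for s in self.states if (p := self.parent[s]) is not None
        )

    @property
    def fusion_pairs(self) -> tuple[tuple[str, str], ...]:
        """Tree edges followed by anchor pairs — the pairs fused by the solver."""
        return self.edges + self.anchor_pairs

    def topological_order(self) -> tuple[str, ...]:
        """Root-first order, stable with respect to the input state order."""
        children: dict[str | None, list[str]] = {}
        for s in self.states:
            children.setdefault(self.parent[s], []).append(s)
        order: list[str] = []
        stack = [self.root]
        while stack:
            s = stack.pop(0)
            order.append(s)
            stack = children.get(s, []) + stack
        return tuple(order)

    def leaves(self) -> tuple[str, ...]:
        has_child = {p for p in self.parent.values() if p is not None}
        return tuple(s for s in self.states if s not in has_child)

    def with_default_anchors(self) -> "StateTree":
        """Add (leaf, root) anchors for every leaf whose parent is not the root."""
        root = self.root
        extra = tuple(
            (leaf, root)
            for leaf in self.leaves()
            if self.parent[leaf] is not None and self.parent[leaf] != root
        )
        return StateTree(self.states, self.parent, self.anchor_pairs + extra)


# ---------------------------------------------------------------------------
# ExpressionPanel
# ---------------------------------------------------------------------------


@dataclass
class ExpressionPanel:
    """Per-state samples x genes expression blocks over one shared gene list.

    Values are log2-scale by convention; the solver assumes they already are.
    """

    genes: tuple[str, ...]
    blocks: dict[str, np.ndarray]
    sample_ids: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise TreeglError("duplicate gene identifiers in panel")
        p = len(self.genes)
        for state, block in self.blocks.items():
            block = np.asarray(block, dtype=float)
            self.blocks[state] = block
            if block.ndim != 2 or block.shape[1] != p:
                raise TreeglError(
                    f"block for state {state!r} has shape {block.shape}, expected (*, {p})"
                )
            if block.shape[0] < 1:
                raise TreeglError(f"state {state!r} has no samples")
            if not np.all(np.isfinite(block)):
                raise TreeglError(f"non-finite expression value in state {state!r}")
            ids = tuple(self.sample_ids.get(state, ()))
            if len(ids) != block.shape[0]:
                raise TreeglError(f"sample id count mismatch for state {state!r}")
            self.sample_ids[state] = ids

    @property
    def p(self) -> int:
        return len(self.genes)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.blocks)

    def n_samples(self, state: str) -> int:
        return self.blocks[state].shape[0]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionPanel":
        idx = [self.genes.index(g) for g in genes]
        return ExpressionPanel(
            genes=tuple(genes),
            blocks={s: b[:, idx] for s, b in self.blocks.items()},
            sample_ids=dict(self.sample_ids),
        )

    def subset_states(self, states: Sequence[str]) -> "ExpressionPanel":
        return ExpressionPanel(
            genes=self.genes,
            blocks={s: self.blocks[s] for s in states},
            sample_ids={s: self.sample_ids[s] for s in states},
        )


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    lambda1: float = 5.0
    lambda2: float = 1.0
    lambda1_grid: tuple[float, ...] = (4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0)
    lambda2_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)
    zero_tol: float = 1e-6
    solver_tol: float = 1e-6
    seed: int = 0
    fc_threshold: float = 1.3
    hub_degree: int = 5
    edge_display_threshold: float = 0.1
    fdr_pathway: float = 0.1
    fdr_go: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise TreeglError("regularization parameters must be non-negative")
        if any(l < 0 for l in tuple(self.lambda1_grid) + tuple(self.lambda2_grid)):
            raise TreeglError("grid values must be non-negative")
        if self.zero_tol <= 0 or self.solver_tol <= 0:
            raise TreeglError("tolerances must be positive")
        if self.fc_threshold <= 1:
            raise TreeglError("fold-change threshold must exceed 1")
        if self.hub_degree <= 0:
            raise TreeglError("hub degree must be positive")
        if self.edge_display_threshold < 0:
            raise TreeglError("edge display threshold must be non-negative")
        for name in ("fdr_pathway", "fdr_go"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise TreeglError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a ``key=value`` configuration file (lists comma-separated)."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise TreeglError(f"malformed config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise TreeglError(f"unknown config key: {key!r}")
            if key.endswith("_grid"):
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("seed", "hub_degree"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------


def read_panel(expr_path: str | Path, samplemap_path: str | Path) -> ExpressionPanel:
    """Read a genes x samples TSV plus a sample -> state map into a panel.

    The expression TSV has a leading gene-identifier column and one column per
    sample; the sample map has columns ``sample_id`` and ``state``.  Samples in
    the matrix but absent from the map are rejected, as are map entries whose
    sample is missing from the matrix.
    """
    expr = pd.read_csv(
        expr_path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
    )
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise TreeglError(f"duplicate gene IDs in expression matrix: {dupes}")
    try:
        values = expr.to_numpy(dtype=float)
    except ValueError as exc:
        raise TreeglError(f"non-numeric expression value: {exc}") from exc
    smap = pd.read_csv(samplemap_path, sep="\t", dtype=str)
    if not {"sample_id", "state"}.issubset(smap.columns):
        raise TreeglError("sample map must have columns sample_id and state")
    missing = [s for s in smap["sample_id"] if s not in expr.columns]
    if missing:
        raise TreeglError(f"samples in map absent from matrix: {missing}")
    unmapped = [c for c in expr.columns if c not in set(smap["sample_id"])]
    if unmapped:
        logger.warning("dropping %d unmapped samples: %s", len(unmapped), unmapped)

    genes = tuple(str(g) for g in expr.index)
    col_of = {c: i for i, c in enumerate(expr.columns)}
    blocks: dict[str, np.ndarray] = {}
    sample_ids: dict[str, tuple[str, ...]] = {}
    for state in smap["state"].drop_duplicates():
        ids = tuple(smap.loc[smap["state"] == state, "sample_id"])
        cols = [col_of[s] for s in ids]
        blocks[state] = values[:, cols].T.copy()
        sample_ids[state] = ids
    return ExpressionPanel(genes=genes, blocks=blocks, sample_ids=sample_ids)


def write_panel(
    panel: ExpressionPanel, expr_path: str | Path, samplemap_path: str | Path
) -> None:
    columns: list[str] = []
    mats: list[np.ndarray] = []
    rows = []
    for state in panel.states:
        for sid in panel.sample_ids[state]:
            rows.append({"sample_id": sid, "state": state})
        columns.extend(panel.sample_ids[state])
        mats.append(panel.blocks[state].T)
    df = pd.DataFrame(np.hstack(mats), index=list(panel.genes), columns=columns)
    df.index.name = "gene"
    df.to_csv(expr_path, sep="\t", float_format=lambda v: repr(float(v)))
    pd.DataFrame(rows).to_csv(samplemap_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tree I/O
# ---------------------------------------------------------------------------


def read_tree(tree_path: str | Path, default_anchors: bool = True) -> StateTree:
    """Read a child/parent/anchor TSV into a validated :class:`StateTree`.

    The root row carries parent ``-``.  A third column, when present, names an
    anchor ancestor for that state.  When the file declares no anchors at all
    and ``default_anchors`` is true, every leaf whose parent is not the root is
    anchored to the root.
    """
    states: list[str] = []
    parent: dict[str, str | None] = {}
    anchors: list[tuple[str, str]] = []
    lines = Path(tree_path).read_text().splitlines()
    for i, raw in enumerate(lines):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if i == 0 and fields[0].lower() == "child":
            continue
        child = fields[0].strip()
        par = fields[1].strip() if len(fields) > 1 else ""
        if not child or not par:
            raise TreeglError(f"malformed tree row: {raw!r}")
        if child in parent:
            raise TreeglError(f"state {child!r} listed twice in tree file")
        states.append(child)
        parent[child] = None if par == "-" else par
        if len(fields) > 2 and fields[2].strip() not in ("", "-"):
            anchors.append((child, fields[2].strip()))
    tree = StateTree(tuple(states), parent, tuple(anchors))
    if default_anchors and not anchors:
        tree = tree.with_default_anchors()
    return tree


def write_tree(tree: StateTree, tree_path: str | Path) -> None:
    anchor_of = dict(tree.anchor_pairs[::-1])  # first anchor per state wins
    with open(tree_path, "w") as fh:
        fh.write("child\tparent\tanchor\n")
        for s in tree.states:
            p = tree.parent[s] or "-"
            a = anchor_of.get(s, "-")
            fh.write(f"{s}\t{p}\t{a}\n")


# ---------------------------------------------------------------------------
# Network edge-list I/O
# ---------------------------------------------------------------------------


def write_networks(networks: Iterable, out_path: str | Path) -> None:
    """Write networks as a TSV of (state, gene_i, gene_j, weight) rows.

    Gene pairs are canonical (``gene_i < gene_j`` lexicographically) and rows
    are sorted by state then pair, so output is deterministic.
    """
    rows = []
    for net in networks:
        for (gi, gj), w in net.edges.items():
            a, b = sorted((gi, gj))
            rows.append((net.state, a, b, w))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(out_path, "w") as fh:
        fh.write("state\tgene_i\tgene_j\tweight\n")
        for state, a, b, w in rows:
            fh.write(f"{state}\t{a}\t{b}\t{float(w)!r}\n")


def read_networks(path: str | Path, genes: Sequence[str] | None = None) -> list:
    """Read an edge-list TSV back into a list of GeneNetwork objects."""
    from .network_ops import GeneNetwork

    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"state": str, "gene_i": str, "gene_j": str},
        float_precision="round_trip",
    )
    nets = []
    universe = tuple(genes) if genes is not None else tuple(
        sorted(set(df["gene_i"]) | set(df["gene_j"]))
    )
    for state in df["state"].drop_duplicates():
        sub = df[df["state"] == state]
        edges = {
            (r.gene_i, r.gene_j): float(r.weight)
            for r in sub.itertuples(index=False)
        }
        nets.append(GeneNetwork(state=state, genes=universe, edges=edges))
    return nets


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
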