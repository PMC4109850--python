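"""Precision-recall evaluation of structure recovery on simulated collections."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, ExpressionPanel, TreeglError
from .network_ops import GeneNetwork, symmetrize_max
from .simulate import TrueNetworkCollection, build_tree_collection, sample_panel
from .solver import STATIC_STATE, fit_all_grid

__all__ = [
    "PRPoint",
    "score_edges",
    "pr_curve",
    "replicate_experiments",
    "METHODS",
]

METHODS = ("treegl", "static", "independent")


def default_lambda1_grid(n_per_state: int) -> tuple[float, ...]:
    """Sparsity grid spanning dense to near-empty fits.

    With an unscaled residual sum of squares the useful lambda1 range grows
    roughly with sqrt(n); the base grid is calibrated for 5 samples per state.
    """
    scale = np.sqrt(max(n_per_state, 1) / 5.0)
    return tuple(float(round(v * scale, 4)) for v in np.geomspace(0.4, 12.0, 8))


@dataclass(frozen=True)
class PRPoint:
    lambda1: float
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise TreeglError("counts must be non-negative")

    @property
    def precision(self) -> float:
        denom = self.TP + self.FP
        return self.TP / denom if denom > 0 else 1.0

    @property
    def recall(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom > 0 else 1.0


def score_edges(estimated: GeneNetwork, truth: np.ndarray) -> tuple[int, int, int]:
    """Undirected presence comparison of an estimated network against a true
    adjacency matrix over the same gene universe; returns (TP, FP, FN)."""
    truth = np.asarray(truth)
    p = len(estimated.genes)
    if truth.shape != (p, p):
        raise TreeglError(
            f"truth adjacency {truth.shape} does not match {p}-gene universe"
        )
    index = {g: i for i, g in enumerate(estimated.genes)}
    est_pairs = set()
    for a, b in estimated.edges:
        i, j = index[a], index[b]
        est_pairs.add((i, j) if i < j else (j, i))
    ii, jj = np.nonzero(np.triu(truth, 1))
    true_pairs = set(zip(ii.tolist(), jj.tolist()))
    tp = len(est_pairs & true_pairs)
    fp = len(est_pairs - true_pairs)
    fn = len(true_pairs - est_pairs)
    return tp, fp, fn


def _networks_for_method(
    method: str,
    collection: TrueNetworkCollection,
    panel: ExpressionPanel,
    lambda1_grid,
    lambda2: float,
    config: AnalysisConfig,
) -> dict[float, dict[str, GeneNetwork]]:
    """Per lambda1: a network for every state (static repeats its single fit)."""
    states = collection.tree.states
    out: dict[float, dict[str, GeneNetwork]] = {}
    if method == "treegl":
        tensors = fit_all_grid(panel, collection.tree, lambda1_grid, lambda2, config)
        for l1, tensor in tensors.items():
            nets = {n.state: n for n in symmetrize_max(tensor)}
            out[l1] = {s: nets[s] for s in states}
    elif method == "independent":
        from .solver import _singleton_tree  # same grid machinery, no fusion

        per_state: dict[str, dict[float, GeneNetwork]] = {}
        for s in states:
            sub = panel.subset_states([s])
            tensors = fit_all_grid(sub, _singleton_tree(s), lambda1_grid, 0.0, config)
            per_state[s] = {
                l1: symmetrize_max(t)[0] for l1, t in tensors.items()
            }
        for l1 in per_state[states[0]]:
            out[l1] = {s: per_state[s][l1] for s in states}
    elif method == "static":
        from .solver import _singleton_tree

        pooled = np.vstack([panel.blocks[s] for s in states])
        ids = tuple(sid for s in states for sid in panel.sample_ids[s])
        sub = ExpressionPanel(
            genes=panel.genes,
            blocks={STATIC_STATE: pooled},
            sample_ids={STATIC_STATE: ids},
        )
        tensors = fit_all_grid(sub, _singleton_tree(STATIC_STATE), lambda1_grid, 0.0, config)
        for l1, tensor in tensors.items():
            net = symmetrize_max(tensor)[0]
            out[l1] = {s: net for s in states}
    else:
        raise TreeglError(f"unknown method {method!r}; choose from {METHODS}")
    return out


def pr_curve(
    method: str,
    collection: TrueNetworkCollection,
    panel: ExpressionPanel,
    lambda1_grid,
    lambda2: float,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trace the lambda1 grid for one method and score every state.

    Returns ``(per_state, pooled)`` data frames.  ``pooled`` micro-averages by
    summing TP/FP/FN over states at each grid value.
    """
    config = config or AnalysisConfig()
    nets_by_lambda = _networks_for_method(
        method, collection, panel, lambda1_grid, lambda2, config
    )
    rows = []
    pooled_rows = []
    for l1 in sorted(nets_by_lambda, reverse=True):
        nets = nets_by_lambda[l1]
        tot_tp = tot_fp = tot_fn = 0
        for state in collection.tree.states:
            tp, fp, fn = score_edges(nets[state], collection.adjacency_for_state(state))
            pt = PRPoint(l1, tp, fp, fn)
            rows.append(
                {
                    "method": method,
                    "lambda1": l1,
                    "state": state,
                    "TP": tp,
                    "FP": fp,
                    "FN": fn,
                    "precision": pt.precision,
                    "recall": pt.recall,
                }
            )
            tot_tp += tp
            tot_fp += fp
            tot_fn += fn
        pooled_pt = PRPoint(l1, tot_tp, tot_fp, tot_fn)
        pooled_rows.append(
            {
                "method": method,
                "lambda1": l1,
                "TP": tot_tp,
                "FP": tot_fp,
                "FN": tot_fn,
                "precision": pooled_pt.precision,
                "recall": pooled_pt.recall,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(pooled_rows)


def replicate_experiments(
    n_reps: int,
    p: int,
    n_per_state: int,
    segment_len: int,
    lambda1_grid,
    lambda2: float,
    seed,
    methods=METHODS,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the simulation/fit/score loop and summarize with quartile bands.

    Returns ``(points, summary)``: per-replicate pooled PR points, and the
    per-method per-grid-value median/Q1/Q3 of precision and recall.
    """
    if n_reps < 1:
        raise TreeglError("n_reps must be at least 1")
    config = config or AnalysisConfig()
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(n_reps)
    all_points = []
    for rep, rep_seed in enumerate(rep_seeds):
        coll_seed, panel_seed = rep_seed.spawn(2)
        collection = build_tree_collection(p, segment_len, coll_seed)
        panel = sample_panel(collection, n_per_state, panel_seed)
        for method in methods:
            _, pooled = pr_curve(
                method, collection, panel, lambda1_grid, lambda2, config
            )
            pooled.insert(0, "replicate", rep)
            all_points.append(pooled)
    points = pd.concat(all_points, ignore_index=True)
    summary = (
        points.groupby(["method", "lambda1"])[["precision", "recall"]]
        .agg(
            precision_median=("precision", "median"),
            precision_q1=("precision", lambda v: float(np.quantile(v, 0.25))),
            precision_q3=("precision", lambda v: float(np.quantile(v, 0.75))),
            recall_median=("recall", "median"),
            recall_q1=("recall", lambda v: float(np.quantile(v, 0.25))),
            recall_q3=("recall", lambda v: float(np.quantile(v, 0.75))),
        )
        .reset_index()
    )
    return points, summary
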