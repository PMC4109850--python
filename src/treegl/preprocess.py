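"""Probe-level normalization, summarization and the gene-variability filter.

PM-only intensities: log2 transform, cyclic-loess normalization across array
pairs, Tukey median-polish summarization per gene, median collapse of
duplicate gene rows, then a between-state fold-change filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_io import ExpressionPanel, TreeglError

logger = logging.getLogger("treegl")

__all__ = [
    "ProbeMatrix",
    "read_probe_matrix",
    "normalize_probe_matrix",
    "median_polish_summarize",
    "collapse_duplicates",
    "fold_change_filter",
]


@dataclass
class ProbeMatrix:
    """Probes x arrays intensity matrix with a probe -> gene map."""

    probes: tuple[str, ...]
    genes: dict[str, str]  # probe -> gene id
    arrays: tuple[str, ...]
    values: np.ndarray
    log2_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.arrays)):
            raise TreeglError("probe matrix shape does not match labels")
        if len(set(self.probes)) != len(self.probes):
            raise TreeglError("duplicate probe identifiers")
        if set(self.genes) != set(self.probes):
            raise TreeglError("every probe must map to exactly one gene")
        if self.log2_scale:
            if not np.all(np.isfinite(self.values)):
                raise TreeglError("non-finite log2 intensity")
        else:
            if not np.all(self.values > 0):
                raise TreeglError("linear-scale intensities must be positive")


def read_probe_matrix(path: str | Path) -> ProbeMatrix:
    """Read a probe TSV with columns probe_id, gene_id, then one per array."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    if not {"probe_id", "gene_id"}.issubset(df.columns):
        raise TreeglError("probe TSV must start with probe_id and gene_id columns")
    arrays = tuple(c for c in df.columns if c not in ("probe_id", "gene_id"))
    return ProbeMatrix(
        probes=tuple(df["probe_id"]),
        genes=dict(zip(df["probe_id"], df["gene_id"])),
        arrays=arrays,
        values=df[list(arrays)].to_numpy(dtype=float),
    )


def normalize_probe_matrix(
    pm: ProbeMatrix, span: float = 0.7, cycles: int = 2
) -> ProbeMatrix:
    """Log2 transform followed by cyclic loess across all array pairs.

    For each ordered pair of arrays a loess curve of M = log-ratio on
    A = average intensity is fitted; half of the fitted M is subtracted from
    one array and added to the other.  All pairs are visited ``cycles`` times.
    """
    if pm.log2_scale:
        raise TreeglError("probe matrix already log2-scale")
    x = np.log2(pm.values)
    k = x.shape[1]
    for _cycle in range(cycles):
        for i in range(k):
            for j in range(i + 1, k):
                m = x[:, i] - x[:, j]
                a = 0.5 * (x[:, i] + x[:, j])
                fit = lowess(m, a, frac=span, return_sorted=False)
                x[:, i] -= fit / 2.0
                x[:, j] += fit / 2.0
    return ProbeMatrix(
        probes=pm.probes, genes=dict(pm.genes), arrays=pm.arrays,
        values=x, log2_scale=True,
    )


def _median_polish(block: np.ndarray, tol: float = 1e-4, max_iter: int = 10):
    """Tukey median polish; returns (overall, row, col, residual)."""
    resid = block.astype(float).copy()
    nr, nc = resid.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rdelta = np.median(resid, axis=1)
        resid -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta
        cdelta = np.median(resid, axis=0)
        resid -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta
        if max(np.abs(rdelta).max(initial=0.0), np.abs(cdelta).max(initial=0.0)) < tol:
            break
    return overall, row, col, resid


def median_polish_summarize(pm: ProbeMatrix) -> pd.DataFrame:
    """Summarize each gene's probes x arrays block to one value per array.

    The gene value for an array is the polish's overall effect plus that
    array's column effect.  Genes appear in first-probe order; a gene with no
    probes cannot occur by construction of :class:`ProbeMatrix`.
    """
    if not pm.log2_scale:
        raise TreeglError("median polish expects a log2-scale probe matrix")
    gene_order: list[str] = []
    gene_rows: dict[str, list[int]] = {}
    for i, probe in enumerate(pm.probes):
        g = pm.genes[probe]
        if g not in gene_rows:
            gene_rows[g] = []
            gene_order.append(g)
        gene_rows[g].append(i)
    out = np.empty((len(gene_order), len(pm.arrays)))
    for r, g in enumerate(gene_order):
        block = pm.values[gene_rows[g], :]
        if block.shape[0] == 1:
            out[r] = block[0]
            continue
        overall, _row, col, _resid = _median_polish(block)
        out[r] = overall + col
    return pd.DataFrame(out, index=gene_order, columns=list(pm.arrays))


def collapse_duplicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace rows sharing a gene id by their per-array median, keeping the
    first-occurrence row order."""
    order = expr.index.drop_duplicates()
    collapsed = expr.groupby(level=0, sort=False).median()
    return collapsed.loc[order]


def fold_change_filter(panel: ExpressionPanel, threshold: float) -> ExpressionPanel:
    """Keep genes whose between-state median fold change exceeds ``threshold``.

    Per gene, the median log2 value is computed within each state; the gene is
    retained iff max over state pairs of 2^|median_a - median_b| > threshold.
    """
    if threshold <= 1:
        raise TreeglError("fold-change threshold must exceed 1")
    medians = np.stack(
        [np.median(panel.blocks[s], axis=0) for s in panel.states]
    )  # states x genes
    spread = medians.max(axis=0) - medians.min(axis=0)
    keep = np.exp2(spread) > threshold
    kept_genes = [g for g, k in zip(panel.genes, keep) if k]
    logger.info("fold-change filter kept %d of %d genes", len(kept_genes), panel.p)
    return panel.subset_genes(kept_genes)
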