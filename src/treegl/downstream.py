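"""Gene-set enrichment, expression screens and quartile-stratified survival."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionPanel, TreeglError

logger = logging.getLogger("treegl")

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "read_survival_table",
    "set_enrichment",
    "adjust_pvalues",
    "anova_screen",
    "pairwise_t_screen",
    "survival_screen",
    "survival_screen_many",
    "SurvivalScreenResult",
]


@dataclass
class GeneSetCollection:
    """Named gene sets tested against a fixed reference universe."""

    sets: dict[str, set[str]]
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.universe)) != len(self.universe):
            raise TreeglError("universe contains duplicate gene ids")
        uni = set(self.universe)
        restricted = {}
        for name, genes in self.sets.items():
            if not genes:
                raise TreeglError(f"gene set {name!r} is empty")
            inside = set(genes) & uni
            if not inside:
                logger.warning("gene set %r has no genes in the universe; dropped", name)
                continue
            restricted[name] = inside
        self.sets = restricted


def read_gmt(path: str | Path, universe) -> GeneSetCollection:
    """Read a GMT file (set name, description, then member genes per line)."""
    sets: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise TreeglError(f"malformed GMT line: {raw[:80]!r}")
        sets[fields[0]] = set(fields[2:])
    return GeneSetCollection(sets=sets, universe=tuple(universe))


def set_enrichment(
    query, collection: GeneSetCollection, test: str = "hypergeometric"
) -> pd.DataFrame:
    """One-sided over-representation p-value per set.

    The hypergeometric tail P(X >= k) and the one-sided Fisher exact test are
    the same test; both are offered and agree to floating-point accuracy.
    """
    if test not in ("hypergeometric", "fisher"):
        raise TreeglError(f"unknown test {test!r}")
    uni = set(collection.universe)
    query = set(query)
    dropped = query - uni
    if dropped:
        logger.warning("dropping %d query genes outside the universe", len(dropped))
    query &= uni
    if not query:
        raise TreeglError("query is empty after restriction to the universe")
    N, n = len(uni), len(query)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(query & members)
        if test == "hypergeometric":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append({"set": name, "set_size": K, "overlap": k, "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = adjust_pvalues(df["p_value"].to_numpy(), method="bh")
    return df


def adjust_pvalues(pvals, method: str = "bh", m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment.

    ``m`` overrides the number of tests (defaults to ``len(pvals)``).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise TreeglError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise TreeglError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise TreeglError("m cannot be smaller than the number of p-values")
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(1.0, adj)
        return out
    raise TreeglError(f"unknown adjustment method {method!r}")


def anova_screen(panel: ExpressionPanel, alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene one-way ANOVA across states with BH adjustment.

    Genes with zero variance everywhere get F=0, p=1 with a warning.
    """
    states = panel.states
    if len(states) < 2:
        raise TreeglError("ANOVA needs at least 2 states")
    for s in states:
        if panel.n_samples(s) < 2:
            raise TreeglError(f"state {s!r} has fewer than 2 samples")
    groups = [panel.blocks[s] for s in states]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*groups, axis=0)
    F = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if np.any(bad):
        logger.warning(
            "%d genes with degenerate variance; p set to 1", int(bad.sum())
        )
        F[~np.isfinite(F)] = 0.0
        p[bad] = 1.0
    adj = adjust_pvalues(p, method="bh")
    return pd.DataFrame(
        {
            "gene": list(panel.genes),
            "F": F,
            "p_value": p,
            "p_adjusted": adj,
            "significant": adj < alpha_fdr,
        }
    )


def pairwise_t_screen(
    panel: ExpressionPanel, state_a: str, state_b: str, alpha_fdr: float
) -> pd.DataFrame:
    """Equal-variance two-sample t-test per gene between two states, BH-adjusted."""
    for s in (state_a, state_b):
        if s not in panel.blocks:
            raise TreeglError(f"unknown state {s!r}")
        if panel.n_samples(s) < 2:
            raise TreeglError(f"state {s!r} has fewer than 2 samples")
    a, b = panel.blocks[state_a], panel.blocks[state_b]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    zero_diff = np.isclose(a.mean(axis=0), b.mean(axis=0))
    bad = ~np.isfinite(p)
    t[bad & zero_diff] = 0.0
    p[bad & zero_diff] = 1.0
    p[bad & ~zero_diff] = 0.0
    adj = adjust_pvalues(p, method="bh")
    return pd.DataFrame(
        {
            "gene": list(panel.genes),
            "t": t,
            "p_value": p,
            "p_adjusted": adj,
            "significant": adj < alpha_fdr,
        }
    )


@dataclass
class SurvivalScreenResult:
    gene: str
    groups: dict[str, pd.DataFrame]  # group -> (time, survival) step curves
    group_sizes: dict[str, int]
    logrank_stat: float
    p_value: float
    rate_at_horizon: dict[str, float]


GROUP_LOW, GROUP_MID, GROUP_HIGH = "lower", "interquartile", "upper"


def _km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def survival_screen(
    gene: str,
    expression: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon_years: float = 15.0,
) -> SurvivalScreenResult:
    """Quartile-stratified Kaplan-Meier screen for one gene.

    Patients split at the 25th/75th expression percentiles (linear
    interpolation) into lower (<= Q1), upper (>= Q3) and interquartile groups;
    a 3-group log-rank test (2 degrees of freedom) compares the curves.
    """
    from lifelines.statistics import multivariate_logrank_test

    expression = np.asarray(expression, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(expression) == len(times) == len(events)):
        raise TreeglError("expression, times and events must have equal length")
    if np.any(times <= 0):
        raise TreeglError("survival times must be positive")
    if not set(np.unique(events)) <= {0, 1}:
        raise TreeglError("event indicator must be binary")
    q1, q3 = np.percentile(expression, [25, 75])
    if q1 == q3:
        raise TreeglError(f"degenerate expression quartiles for gene {gene!r}")
    labels = np.where(
        expression <= q1, GROUP_LOW, np.where(expression >= q3, GROUP_HIGH, GROUP_MID)
    )
    groups: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    rates: dict[str, float] = {}
    for name in (GROUP_LOW, GROUP_MID, GROUP_HIGH):
        mask = labels == name
        sizes[name] = int(mask.sum())
        if sizes[name] < 3:
            raise TreeglError(
                f"group {name!r} has {sizes[name]} patients; need at least 3"
            )
        curve = _km_curve(times[mask], events[mask])
        groups[name] = curve
        at_or_before = curve[curve["time"] <= horizon_years]
        rates[name] = float(at_or_before["survival"].iloc[-1]) if len(at_or_before) else 1.0
    lr = multivariate_logrank_test(times, labels, events)
    return SurvivalScreenResult(
        gene=gene,
        groups=groups,
        group_sizes=sizes,
        logrank_stat=float(lr.test_statistic),
        p_value=float(lr.p_value),
        rate_at_horizon=rates,
    )


def survival_screen_many(
    table: pd.DataFrame,
    genes,
    horizon_years: float = 15.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen several hub genes, Bonferroni-correcting across the hubs tested.

    ``table`` needs columns ``time_years`` and ``event`` plus one expression
    column per gene.
    """
    rows = []
    for gene in genes:
        if gene not in table.columns:
            raise TreeglError(f"no expression column for gene {gene!r}")
        res = survival_screen(
            gene,
            table[gene].to_numpy(),
            table["time_years"].to_numpy(),
            table["event"].to_numpy(),
            horizon_years,
        )
        rows.append(
            {
                "gene": gene,
                "logrank_stat": res.logrank_stat,
                "p_value": res.p_value,
                **{f"rate_{k}": v for k, v in res.rate_at_horizon.items()},
            }
        )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = adjust_pvalues(df["p_value"].to_numpy(), method="bonferroni")
    df["significant"] = df["p_bonferroni"] < alpha
    return df


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival CSV with columns sample, time_years, event, then
    optional per-gene expression columns."""
    df = pd.read_csv(path)
    required = {"sample", "time_years", "event"}
    if not required.issubset(df.columns):
        raise TreeglError(f"survival table must have columns {sorted(required)}")
    if np.any(df["time_years"].to_numpy(dtype=float) <= 0):
        raise TreeglError("survival times must be positive")
    if not set(df["event"].unique()) <= {0, 1}:
        raise TreeglError("event indicator must be binary")
    return df
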