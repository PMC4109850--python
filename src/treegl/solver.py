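"""Joint sparse neighborhood regression across tree-related states.

For one response gene g the estimator minimizes, over per-state coefficient
vectors beta^t (one weight per other gene),

    sum_t 0.5 * ||y^t - X^t beta^t||^2
      + lambda1 * sum_t ||beta^t||_1
      + lambda2 * sum_{(c, pi(c))} ||beta^c - beta^{pi(c)}||_1
      + lambda2 * sum_{(s, a) anchors} ||beta^s - beta^a||_1

i.e. a lasso term per state plus total-variation fusion along tree edges and
anchor pairs.  The problem is convex; we solve it with ADMM on the generalized
lasso form min f(B) + h(DB), where D stacks an identity block (sparsity) and a
signed incidence block (fusion differences).  The quadratic step uses the
Woodbury identity: the sample count sum_t n_t is far below the variable count
T*(p-1), so each iteration costs only small matrix products after one n x n
Cholesky factorization.

Per-state blocks are mean-centered before fitting; no variance scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .core_io import AnalysisConfig, ExpressionPanel, StateTree, TreeglError

logger = logging.getLogger("treegl")

__all__ = [
    "NeighborhoodProblem",
    "CoefficientTensor",
    "objective_value",
    "fit_gene",
    "fit_all",
    "fit_all_grid",
    "fit_independent",
    "fit_static",
    "lambda_max",
]


@dataclass
class NeighborhoodProblem:
    """One gene's joint regression problem across all states."""

    gene: str
    states: tuple[str, ...]
    y: dict[str, np.ndarray]  # state -> (n_t,)
    X: dict[str, np.ndarray]  # state -> (n_t, p-1)
    predictors: tuple[str, ...]  # column gene ids, excludes ``gene``
    lambda1: float
    lambda2: float
    fusion_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.gene in self.predictors:
            raise TreeglError("design columns must exclude the response gene")
        q = len(self.predictors)
        for s in self.states:
            y = np.asarray(self.y[s], dtype=float)
            X = np.asarray(self.X[s], dtype=float)
            if X.shape != (y.shape[0], q):
                raise TreeglError(
                    f"state {s!r}: design shape {X.shape} does not match "
                    f"response length {y.shape[0]} and {q} predictors"
                )
            self.y[s] = y
            self.X[s] = X
        sset = set(self.states)
        for a, b in self.fusion_pairs:
            if a not in sset or b not in sset:
                raise TreeglError(f"fusion pair ({a!r}, {b!r}) references unknown state")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise TreeglError("penalties must be non-negative")

    @property
    def q(self) -> int:
        return len(self.predictors)


@dataclass
class CoefficientTensor:
    """Per-state p x p coefficient matrices; row g holds gene g's regression."""

    genes: tuple[str, ...]
    coef: dict[str, np.ndarray]  # state -> (p, p), zero diagonal

    def __post_init__(self) -> None:
        p = len(self.genes)
        for state, B in self.coef.items():
            B = np.asarray(B, dtype=float)
            if B.shape != (p, p):
                raise TreeglError(f"coefficient matrix for {state!r} must be {p}x{p}")
            if not np.all(np.isfinite(B)):
                raise TreeglError(f"non-finite coefficient in state {state!r}")
            if np.any(np.diag(B) != 0):
                raise TreeglError(f"nonzero diagonal in state {state!r}")
            self.coef[state] = B

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.coef)


def objective_value(
    problem: NeighborhoodProblem, betas: dict[str, np.ndarray]
) -> float:
    """Evaluate the 4-term objective at the given per-state coefficients."""
    total = 0.0
    for s in problem.states:
        b = np.asarray(betas[s], dtype=float)
        if b.shape != (problem.q,):
            raise TreeglError(
                f"beta for state {s!r} has shape {b.shape}, expected ({problem.q},)"
            )
        r = problem.y[s] - problem.X[s] @ b
        total += 0.5 * float(r @ r) + problem.lambda1 * float(np.abs(b).sum())
    for a, b_ in problem.fusion_pairs:
        total += problem.lambda2 * float(np.abs(betas[a] - betas[b_]).sum())
    return total


def _soft(x: np.ndarray, thresh) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thresh, 0.0)


class _AdmmWorkspace:
    """Factorizations reusable across lambda values for one gene's problem."""

    def __init__(self, problem: NeighborhoodProblem):
        self.problem = problem
        states = problem.states
        self.T = len(states)
        self.q = problem.q
        self.idx = {s: t for t, s in enumerate(states)}
        m = len(problem.fusion_pairs)
        self.m = m
        # signed incidence: row r is +1 at the first state, -1 at the second
        L = np.zeros((m, self.T))
        for r, (a, b) in enumerate(problem.fusion_pairs):
            L[r, self.idx[a]] += 1.0
            L[r, self.idx[b]] -= 1.0
        self.L = L
        DtD = np.eye(self.T) + L.T @ L
        self.S = np.linalg.inv(DtD)  # (D^T D)^{-1}, applied per coordinate
        self.Xs = [problem.X[s] for s in states]
        self.ys = [problem.y[s] for s in states]
        self.ns = [x.shape[0] for x in self.Xs]
        self.offsets = np.concatenate([[0], np.cumsum(self.ns)])
        self.n = int(self.offsets[-1])
        self.C = np.stack([self.Xs[t].T @ self.ys[t] for t in range(self.T)])
        # Woodbury pays off only when the total sample count is below the
        # variable count T*q; otherwise factor the T*q x T*q Hessian directly.
        self.use_woodbury = self.n < self.T * self.q
        if self.use_woodbury:
            # W = X K^{-1} X^T with K = kron(D^T D, I_q); block (t,s) = S_ts X_t X_s^T
            W = np.zeros((self.n, self.n))
            for t in range(self.T):
                rt = slice(self.offsets[t], self.offsets[t + 1])
                for s in range(t, self.T):
                    if self.S[t, s] == 0.0:
                        continue
                    rs = slice(self.offsets[s], self.offsets[s + 1])
                    blk = self.S[t, s] * (self.Xs[t] @ self.Xs[s].T)
                    W[rt, rs] = blk
                    if s != t:
                        W[rs, rt] = blk.T
            self.W = W
        else:
            H0 = np.zeros((self.T * self.q, self.T * self.q))
            for t in range(self.T):
                sl = slice(t * self.q, (t + 1) * self.q)
                H0[sl, sl] = self.Xs[t].T @ self.Xs[t]
            self.H0 = H0
            self.K = np.kron(DtD, np.eye(self.q))
        self._cho = None
        self._rho = None

    def factor(self, rho: float) -> None:
        if self._rho == rho and self._cho is not None:
            return
        if self.use_woodbury:
            F = np.eye(self.n) + self.W / rho
        else:
            F = self.H0 + rho * self.K
        self._cho = cho_factor(F, lower=True)
        self._rho = rho

    def apply_X(self, B: np.ndarray) -> np.ndarray:
        out = np.empty(self.n)
        for t in range(self.T):
            out[self.offsets[t]: self.offsets[t + 1]] = self.Xs[t] @ B[t]
        return out

    def apply_Xt(self, v: np.ndarray) -> np.ndarray:
        out = np.empty((self.T, self.q))
        for t in range(self.T):
            out[t] = self.Xs[t].T @ v[self.offsets[t]: self.offsets[t + 1]]
        return out

    def apply_D(self, B: np.ndarray) -> np.ndarray:
        if self.m == 0:
            return B
        return np.vstack([B, self.L @ B])

    def apply_Dt(self, V: np.ndarray) -> np.ndarray:
        out = V[: self.T].copy()
        if self.m:
            out += self.L.T @ V[self.T:]
        return out

    def h_solve(self, R: np.ndarray, rho: float) -> np.ndarray:
        """Solve (rho*K + X^T X) B = R; R and B are (T, q)."""
        if not self.use_woodbury:
            return cho_solve(self._cho, R.ravel()).reshape(self.T, self.q)
        t1 = (self.S @ R) / rho
        w = self.apply_X(t1)
        s = cho_solve(self._cho, w)
        t2 = (self.S @ self.apply_Xt(s)) / rho
        return t1 - t2


def fit_gene(
    problem: NeighborhoodProblem,
    solver_tol: float = 1e-6,
    zero_tol: float = 1e-6,
    max_iter: int = 100_000,
    rho: float = 1.0,
    workspace: _AdmmWorkspace | None = None,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    return_state: bool = False,
):
    """Minimize the joint neighborhood objective for one gene by ADMM.

    Returns per-state coefficient vectors with entries below ``zero_tol``
    truncated to exact zeros.  Raises if the primal/dual residuals fail to
    reach the tolerance implied by ``solver_tol`` within ``max_iter``
    iterations.
    """
    for s in problem.states:
        if problem.y[s].shape[0] < 2:
            raise TreeglError(
                f"state {s!r} has fewer than 2 samples; cannot fit gene {problem.gene!r}"
            )
    ws = workspace if workspace is not None else _AdmmWorkspace(problem)
    T, q, m = ws.T, ws.q, ws.m
    lam = np.empty((T + m, 1))
    lam[:T] = problem.lambda1
    lam[T:] = problem.lambda2

    if warm is not None:
        z, u = warm[0].copy(), warm[1].copy()
    else:
        z = np.zeros((T + m, q))
        u = np.zeros((T + m, q))

    # residual tolerance: driving the ADMM residuals two orders below
    # solver_tol empirically keeps the objective gap under solver_tol
    eps = max(solver_tol * 1e-2, 1e-12)
    nD = np.sqrt((T + m) * q)
    nB = np.sqrt(T * q)

    ws.factor(rho)
    B = np.zeros((T, q))
    converged = False
    for it in range(max_iter):
        R = ws.C + rho * ws.apply_Dt(z - u)
        B = ws.h_solve(R, rho)
        DB = ws.apply_D(B)
        z_old = z
        z = _soft(DB + u, lam / rho)
        u = u + DB - z
        r_norm = float(np.linalg.norm(DB - z))
        s_norm = rho * float(np.linalg.norm(ws.apply_Dt(z - z_old)))
        eps_pri = nD * eps + eps * max(np.linalg.norm(DB), np.linalg.norm(z))
        eps_dua = nB * eps + eps * rho * float(np.linalg.norm(ws.apply_Dt(u)))
        if r_norm <= eps_pri and s_norm <= eps_dua:
            converged = True
            break
        if it % 50 == 49:  # adaptive penalty, refactor on change
            if r_norm > 10 * s_norm:
                rho *= 2.0
                u /= 2.0
                ws.factor(rho)
            elif s_norm > 10 * r_norm:
                rho /= 2.0
                u *= 2.0
                ws.factor(rho)

    if not converged:
        betas_tmp = {s: z[ws.idx[s]] for s in problem.states}
        gap_proxy = float(np.linalg.norm(ws.apply_D(B) - z))
        raise TreeglError(
            f"ADMM did not converge for gene {problem.gene!r} within {max_iter} "
            f"iterations (primal residual {gap_proxy:.3e}, "
            f"objective {objective_value(problem, betas_tmp):.6g})"
        )

    # the z-block carries exact zeros from the soft threshold
    out = {}
    for s in problem.states:
        b = z[ws.idx[s]].copy()
        b[np.abs(b) <= zero_tol] = 0.0
        out[s] = b
    if return_state:
        return out, (z, u, rho)
    return out


def lambda_max(panel: ExpressionPanel, center: bool = True) -> float:
    """Smallest lambda1 that guarantees the all-zero solution for any lambda2.

    Per-state stationarity at zero holds when lambda1 >= |X_t^T y_t| entrywise
    for every state and gene, with all fusion subgradients set to zero.
    """
    best = 0.0
    for state in panel.states:
        blk = panel.blocks[state]
        if center:
            blk = blk - blk.mean(axis=0, keepdims=True)
        G = np.abs(blk.T @ blk)
        np.fill_diagonal(G, 0.0)
        best = max(best, float(G.max()))
    return best


def _centered_blocks(panel: ExpressionPanel, states) -> dict[str, np.ndarray]:
    return {
        s: panel.blocks[s] - panel.blocks[s].mean(axis=0, keepdims=True)
        for s in states
    }


def _build_problem(
    gene_idx: int,
    genes: tuple[str, ...],
    states: tuple[str, ...],
    blocks: dict[str, np.ndarray],
    lambda1: float,
    lambda2: float,
    fusion_pairs: tuple[tuple[str, str], ...],
) -> NeighborhoodProblem:
    cols = [j for j in range(len(genes)) if j != gene_idx]
    return NeighborhoodProblem(
        gene=genes[gene_idx],
        states=states,
        y={s: blocks[s][:, gene_idx] for s in states},
        X={s: blocks[s][:, cols] for s in states},
        predictors=tuple(genes[j] for j in cols),
        lambda1=lambda1,
        lambda2=lambda2,
        fusion_pairs=fusion_pairs,
    )


def fit_all_grid(
    panel: ExpressionPanel,
    tree: StateTree,
    lambda1_grid,
    lambda2: float,
    config: AnalysisConfig | None = None,
) -> dict[float, CoefficientTensor]:
    """Fit the joint model for every lambda1 in a grid, sharing per-gene
    factorizations and warm starts across the grid (largest lambda first)."""
    config = config or AnalysisConfig()
    states = tree.topological_order()
    missing = [s for s in states if s not in panel.blocks]
    if missing:
        raise TreeglError(f"tree states missing from panel: {missing}")
    blocks = _centered_blocks(panel, states)
    genes = panel.genes
    p = len(genes)
    grid = sorted(set(float(l) for l in lambda1_grid), reverse=True)
    tensors = {
        l1: {s: np.zeros((p, p)) for s in states} for l1 in grid
    }
    for g in range(p):
        problem = _build_problem(g, genes, states, blocks, grid[0], lambda2, tree.fusion_pairs)
        ws = _AdmmWorkspace(problem)
        warm = None
        cols = [j for j in range(p) if j != g]
        for l1 in grid:
            problem.lambda1 = l1
            try:
                betas, warm_state = fit_gene(
                    problem,
                    solver_tol=config.solver_tol,
                    zero_tol=config.zero_tol,
                    workspace=ws,
                    warm=warm,
                    return_state=True,
                )
            except TreeglError as exc:
                raise TreeglError(f"fit failed for gene {genes[g]!r}: {exc}") from exc
            warm = warm_state[:2]
            for s in states:
                tensors[l1][s][g, cols] = betas[s]
    return {
        l1: CoefficientTensor(genes=genes, coef=tensors[l1]) for l1 in grid
    }


def fit_all(
    panel: ExpressionPanel, tree: StateTree, config: AnalysisConfig | None = None
) -> CoefficientTensor:
    """Joint fit of all p neighborhood problems at (config.lambda1, config.lambda2)."""
    config = config or AnalysisConfig()
    out = fit_all_grid(panel, tree, [config.lambda1], config.lambda2, config)
    return out[float(config.lambda1)]


def _singleton_tree(state: str) -> StateTree:
    return StateTree((state,), {state: None}, ())


def fit_independent(
    panel: ExpressionPanel, config: AnalysisConfig | None = None
) -> CoefficientTensor:
    """Per-state lasso networks with no fusion (each state fit on its own)."""
    config = config or AnalysisConfig()
    coef: dict[str, np.ndarray] = {}
    for state in panel.states:
        sub = panel.subset_states([state])
        tensor = fit_all(sub, _singleton_tree(state), config)
        coef[state] = tensor.coef[state]
    return CoefficientTensor(genes=panel.genes, coef=coef)


STATIC_STATE = "static"


def fit_static(
    panel: ExpressionPanel, config: AnalysisConfig | None = None
) -> CoefficientTensor:
    """Single network from all states' samples pooled into one block."""
    config = config or AnalysisConfig()
    pooled = np.vstack([panel.blocks[s] for s in panel.states])
    if pooled.shape[0] < 2:
        raise TreeglError("static fit needs at least 2 samples in total")
    ids = tuple(
        sid for s in panel.states for sid in panel.sample_ids[s]
    )
    sub = ExpressionPanel(
        genes=panel.genes,
        blocks={STATIC_STATE: pooled},
        sample_ids={STATIC_STATE: ids},
    )
    return fit_all(sub, _singleton_tree(STATIC_STATE), config)
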