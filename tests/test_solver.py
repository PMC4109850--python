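import numpy as np
import pytest
from sklearn.linear_model import Lasso

from treegl.core_io import AnalysisConfig, ExpressionPanel, StateTree, TreeglError
from treegl.simulate import build_tree_collection, sample_panel
from treegl.solver import (
    CoefficientTensor,
    NeighborhoodProblem,
    fit_all,
    fit_all_grid,
    fit_gene,
    fit_independent,
    fit_static,
    lambda_max,
    objective_value,
)

from .oracles import slsqp_joint_lasso


def random_problem(rng, T=None, p=None, n=5, lam1=None, lam2=None):
    T = T if T is not None else int(rng.integers(1, 4))
    p = p if p is not None else int(rng.integers(3, 7))
    q = p - 1
    states = tuple(f"t{i}" for i in range(T))
    fusion = tuple((states[i], states[i - 1]) for i in range(1, T))
    X = {s: rng.standard_normal((n, q)) for s in states}
    beta = rng.standard_normal(q) * (rng.random(q) < 0.5)
    y = {s: X[s] @ beta + 0.3 * rng.standard_normal(n) for s in states}
    return NeighborhoodProblem(
        gene="g",
        states=states,
        y=y,
        X=X,
        predictors=tuple(f"x{i}" for i in range(q)),
        lambda1=lam1 if lam1 is not None else float(rng.uniform(0.2, 3)),
        lambda2=lam2 if lam2 is not None else float(rng.uniform(0.1, 2)),
        fusion_pairs=fusion,
    )


class TestObjective:
    def test_zero_betas_is_half_sum_of_squares(self):
        rng = np.random.default_rng(0)
        prob = random_problem(rng, T=2, p=4)
        zeros = {s: np.zeros(prob.q) for s in prob.states}
        expected = 0.5 * sum(float(prob.y[s] @ prob.y[s]) for s in prob.states)
        assert objective_value(prob, zeros) == pytest.approx(expected)

    def test_single_state_independent_of_lambda2(self):
        rng = np.random.default_rng(1)
        prob = random_problem(rng, T=1, p=5, lam2=0.7)
        betas = {prob.states[0]: rng.standard_normal(prob.q)}
        v1 = objective_value(prob, betas)
        prob.lambda2 = 1e6
        assert objective_value(prob, betas) == v1

    def test_matches_term_by_term_hand_computation(self):
        # independent arithmetic oracle, written out long-hand
        rng = np.random.default_rng(2)
        prob = random_problem(rng, T=3, p=4, lam1=1.3, lam2=0.4)
        betas = {s: rng.standard_normal(prob.q) for s in prob.states}
        total = 0.0
        for s in prob.states:
            resid = prob.y[s] - prob.X[s].dot(betas[s])
            total += 0.5 * sum(r * r for r in resid)
            total += 1.3 * sum(abs(b) for b in betas[s])
        for a, b in prob.fusion_pairs:
            total += 0.4 * sum(abs(u - v) for u, v in zip(betas[a], betas[b]))
        assert objective_value(prob, betas) == pytest.approx(total, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        prob = random_problem(rng, T=1, p=4)
        with pytest.raises(TreeglError):
            objective_value(prob, {prob.states[0]: np.zeros(prob.q + 1)})


class TestFitGene:
    def test_matches_generic_convex_solver(self):
        # 20 random instances, p<=6, T<=3, n=5; objective within 1e-5
        rng = np.random.default_rng(0)
        for _ in range(20):
            prob = random_problem(rng)
            ours = fit_gene(prob, solver_tol=1e-7, zero_tol=1e-10)
            ref = slsqp_joint_lasso(prob)
            assert objective_value(prob, ours) <= objective_value(prob, ref) + 1e-5

    def test_single_state_matches_sklearn_lasso(self):
        rng = np.random.default_rng(4)
        n, q = 30, 6
        X = rng.standard_normal((n, q))
        y = X @ np.array([1.0, -0.5, 0, 0, 0.8, 0]) + 0.1 * rng.standard_normal(n)
        lam1 = 2.0
        prob = NeighborhoodProblem(
            gene="g",
            states=("t0",),
            y={"t0": y},
            X={"t0": X},
            predictors=tuple(f"x{i}" for i in range(q)),
            lambda1=lam1,
            lambda2=0.0,
        )
        ours = fit_gene(prob, solver_tol=1e-8, zero_tol=1e-10)["t0"]
        ref = Lasso(alpha=lam1 / n, fit_intercept=False, tol=1e-12, max_iter=100000)
        ref.fit(X, y)
        np.testing.assert_allclose(ours, ref.coef_, atol=1e-4)

    def test_lambda_max_gives_all_zero(self):
        rng = np.random.default_rng(5)
        genes = tuple(f"g{i}" for i in range(5))
        blocks = {s: rng.standard_normal((4, 5)) for s in ("a", "b")}
        panel = ExpressionPanel(
            genes=genes,
            blocks=blocks,
            sample_ids={s: tuple(f"{s}{i}" for i in range(4)) for s in blocks},
        )
        tree = StateTree(("a", "b"), {"a": None, "b": "a"})
        lmax = lambda_max(panel)
        for lam2 in (0.0, 1.0, 100.0):
            cfg = AnalysisConfig(lambda1=lmax * 1.001, lambda2=lam2)
            tensor = fit_all(panel, tree, cfg)
            for s in tensor.states:
                assert np.all(tensor.coef[s] == 0)
        # just below lambda_max something survives
        cfg = AnalysisConfig(lambda1=lmax * 0.5, lambda2=0.0)
        tensor = fit_all(panel, tree, cfg)
        assert any(np.any(tensor.coef[s] != 0) for s in tensor.states)

    def test_huge_lambda2_equalizes_states(self):
        rng = np.random.default_rng(6)
        prob = random_problem(rng, T=3, p=4, lam1=0.3, lam2=1e6)
        betas = fit_gene(prob, solver_tol=1e-8, zero_tol=1e-12)
        b0 = betas[prob.states[0]]
        for s in prob.states[1:]:
            np.testing.assert_allclose(betas[s], b0, atol=1e-4)

    def test_insufficient_samples_rejected(self):
        rng = np.random.default_rng(7)
        prob = random_problem(rng, T=1, p=4, n=1)
        with pytest.raises(TreeglError, match="fewer than 2"):
            fit_gene(prob)


@pytest.fixture(scope="module")
def small_panel_tree():
    rng = np.random.default_rng(8)
    genes = ("gA", "gB", "gC", "gD")
    states = ("S1", "S2", "S3")
    blocks = {s: rng.standard_normal((5, 4)) for s in states}
    panel = ExpressionPanel(
        genes=genes,
        blocks=blocks,
        sample_ids={s: tuple(f"{s}_{i}" for i in range(5)) for s in states},
    )
    tree = StateTree(states, {"S1": None, "S2": "S1", "S3": "S2"})
    return panel, tree


class TestFitAll:
    def test_rows_equal_fit_gene(self, small_panel_tree):
        panel, tree = small_panel_tree
        cfg = AnalysisConfig(lambda1=0.5, lambda2=0.3)
        tensor = fit_all(panel, tree, cfg)
        centered = {
            s: panel.blocks[s] - panel.blocks[s].mean(axis=0) for s in tree.states
        }
        for g, gene in enumerate(panel.genes):
            cols = [j for j in range(panel.p) if j != g]
            prob = NeighborhoodProblem(
                gene=gene,
                states=tree.states,
                y={s: centered[s][:, g] for s in tree.states},
                X={s: centered[s][:, cols] for s in tree.states},
                predictors=tuple(panel.genes[j] for j in cols),
                lambda1=0.5,
                lambda2=0.3,
                fusion_pairs=tree.fusion_pairs,
            )
            betas = fit_gene(prob, solver_tol=cfg.solver_tol, zero_tol=cfg.zero_tol)
            for s in tree.states:
                np.testing.assert_allclose(
                    tensor.coef[s][g, cols], betas[s], atol=1e-6
                )

    def test_permutation_equivariance(self, small_panel_tree):
        panel, tree = small_panel_tree
        cfg = AnalysisConfig(lambda1=0.5, lambda2=0.3, solver_tol=1e-8)
        tensor = fit_all(panel, tree, cfg)
        perm = [2, 0, 3, 1]
        permuted = ExpressionPanel(
            genes=tuple(panel.genes[i] for i in perm),
            blocks={s: panel.blocks[s][:, perm] for s in panel.states},
            sample_ids=dict(panel.sample_ids),
        )
        tensor_p = fit_all(permuted, tree, cfg)
        inv = np.argsort(perm)
        for s in tree.states:
            np.testing.assert_allclose(
                tensor_p.coef[s][np.ix_(inv, inv)], tensor.coef[s], atol=1e-5
            )

    def test_all_zero_at_large_lambda(self, small_panel_tree):
        panel, tree = small_panel_tree
        cfg = AnalysisConfig(lambda1=1e4, lambda2=1.0)
        tensor = fit_all(panel, tree, cfg)
        for s in tensor.states:
            assert np.all(tensor.coef[s] == 0)

    def test_zero_diagonal_and_finite(self, small_panel_tree):
        panel, tree = small_panel_tree
        tensor = fit_all(panel, tree, AnalysisConfig(lambda1=0.2, lambda2=0.1))
        for s in tensor.states:
            assert np.all(np.isfinite(tensor.coef[s]))
            assert np.all(np.diag(tensor.coef[s]) == 0)

    def test_regularization_path_sanity(self, small_panel_tree):
        panel, tree = small_panel_tree
        lmax = lambda_max(panel)
        tensors = fit_all_grid(panel, tree, [0.1 * lmax, 0.9 * lmax], 0.2)
        nnz = {
            l1: sum(int((t.coef[s] != 0).sum()) for s in t.states)
            for l1, t in tensors.items()
        }
        assert nnz[0.1 * lmax] >= nnz[0.9 * lmax]


class TestBaselines:
    def test_independent_equals_fit_all_without_fusion(self, small_panel_tree):
        panel, tree = small_panel_tree
        cfg = AnalysisConfig(lambda1=0.8, lambda2=5.0, solver_tol=1e-8)
        indep = fit_independent(panel, cfg)
        cfg0 = AnalysisConfig(lambda1=0.8, lambda2=0.0, solver_tol=1e-8)
        joint = fit_all(panel, tree, cfg0)
        for s in panel.states:
            np.testing.assert_allclose(indep.coef[s], joint.coef[s], atol=1e-5)

    def test_single_state_panel(self, small_panel_tree):
        panel, _ = small_panel_tree
        sub = panel.subset_states(["S1"])
        cfg = AnalysisConfig(lambda1=0.5, lambda2=1.0)
        indep = fit_independent(sub, cfg)
        tree1 = StateTree(("S1",), {"S1": None})
        joint = fit_all(sub, tree1, cfg)
        np.testing.assert_allclose(indep.coef["S1"], joint.coef["S1"], atol=1e-7)

    def test_single_sample_state_rejected(self):
        panel = ExpressionPanel(
            genes=("a", "b", "c"),
            blocks={"S": np.random.default_rng(0).standard_normal((1, 3))},
            sample_ids={"S": ("x",)},
        )
        with pytest.raises(TreeglError):
            fit_independent(panel, AnalysisConfig(lambda1=1.0))

    def test_static_pools_samples(self, small_panel_tree):
        panel, _ = small_panel_tree
        cfg = AnalysisConfig(lambda1=0.8, lambda2=0.0, solver_tol=1e-8)
        static = fit_static(panel, cfg)
        assert static.states == ("static",)
        # independent fit on the explicitly pooled panel must agree
        pooled = np.vstack([panel.blocks[s] for s in panel.states])
        pooled_panel = ExpressionPanel(
            genes=panel.genes,
            blocks={"static": pooled},
            sample_ids={"static": tuple(f"x{i}" for i in range(pooled.shape[0]))},
        )
        ref = fit_independent(pooled_panel, cfg)
        np.testing.assert_allclose(static.coef["static"], ref.coef["static"], atol=1e-7)

    def test_static_equals_independent_for_one_state(self, small_panel_tree):
        panel, _ = small_panel_tree
        sub = panel.subset_states(["S2"])
        cfg = AnalysisConfig(lambda1=0.6, solver_tol=1e-8)
        static = fit_static(sub, cfg)
        indep = fit_independent(sub, cfg)
        np.testing.assert_allclose(
            static.coef["static"], indep.coef["S2"], atol=1e-6
        )

    def test_static_and_independent_agree_under_shared_truth(self):
        # two states drawn from one distribution, generous n: same support
        rng = np.random.default_rng(10)
        from treegl.simulate import adjacency_to_precision, generate_root_network
        from scipy.linalg import solve_triangular

        p, n = 6, 2000
        adj = generate_root_network(p, seed=3)
        omega = adjacency_to_precision(adj, 0.4, 0.4, seed=4)
        L = np.linalg.cholesky(omega)
        draw = lambda: solve_triangular(
            L.T, rng.standard_normal((p, n)), lower=False
        ).T
        panel = ExpressionPanel(
            genes=tuple(f"g{i}" for i in range(p)),
            blocks={"a": draw(), "b": draw()},
            sample_ids={
                s: tuple(f"{s}{i}" for i in range(n)) for s in ("a", "b")
            },
        )
        cfg = AnalysisConfig(lambda1=30.0, zero_tol=0.05)
        static = fit_static(panel, cfg)
        cfg_ind = AnalysisConfig(lambda1=15.0, zero_tol=0.05)
        indep = fit_independent(panel, cfg_ind)
        support_static = static.coef["static"] != 0
        for s in ("a", "b"):
            assert np.array_equal(indep.coef[s] != 0, support_static)


class TestConsistency:
    def test_support_recovery_at_large_n(self):
        # parameter recovery: with ample data some grid lambda1 recovers the
        # exact support of every distinct network after max-symmetrization
        from treegl.evaluate import score_edges
        from treegl.network_ops import symmetrize_max

        coll = build_tree_collection(10, 3, seed=4, weight_low=0.3, weight_high=0.3)
        panel = sample_panel(coll, 1000, seed=104)
        cfg = AnalysisConfig(solver_tol=1e-5, zero_tol=0.08)
        tensors = fit_all_grid(panel, coll.tree, [1.0, 7.0], 15.0, cfg)
        exact = []
        for l1, tensor in tensors.items():
            nets = {n.state: n for n in symmetrize_max(tensor)}
            errs = sum(
                sum(score_edges(nets[s], coll.adjacency_for_state(s))[1:])
                for s in coll.tree.states
            )
            exact.append(errs == 0)
        assert any(exact)


class TestCoefficientTensor:
    def test_nonzero_diagonal_rejected(self):
        B = np.eye(3)
        with pytest.raises(TreeglError):
            CoefficientTensor(genes=("a", "b", "c"), coef={"s": B})

    def test_nonfinite_rejected(self):
        B = np.zeros((2, 2))
        B[0, 1] = np.inf
        with pytest.raises(TreeglError):
            CoefficientTensor(genes=("a", "b"), coef={"s": B})
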