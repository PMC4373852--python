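import numpy as np
import pytest

from lsgrn import (
    CandidateSet,
    InferenceError,
    RunConfig,
    binarize_coefficients,
    build_linear_system,
    generate_truth,
    infer_module,
    select_candidate_set,
    simulate_expression,
    solve_coefficients,
)
from lsgrn.decomposition import ModulePartition
from lsgrn.inference import CoefficientVector, LinearSystem

from conftest import make_expr, make_mi


def truth_partition(truth):
    """Partition directly from the planted module labels."""
    n_modules = max(truth.module_labels.values()) + 1
    modules = [[] for _ in range(n_modules)]
    for g in truth.gene_ids:
        modules[truth.module_labels[g]].append(g)
    return ModulePartition(list(truth.gene_ids), modules, [])


class TestSelectCandidateSet:
    def _mi(self, n, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        return make_mi(vals)

    def test_fraction_one_keeps_every_external_gene(self):
        mi = self._mi(9)
        part = ModulePartition(mi.gene_ids, [mi.gene_ids[:4], mi.gene_ids[4:7], mi.gene_ids[7:]], [])
        cand = select_candidate_set(0, part, mi, 1.0)
        assert sorted(cand.external_genes) == sorted(mi.gene_ids[4:])

    def test_five_percent_of_twenty_pairs_keeps_one_gene(self):
        mi = self._mi(9, seed=3)
        part = ModulePartition(mi.gene_ids, [mi.gene_ids[:4], mi.gene_ids[4:]], [])
        cand = select_candidate_set(0, part, mi, 0.05)
        # ceil(0.05 * 4*5) = 1 pair kept; its external endpoint
        order = {g: i for i, g in enumerate(mi.gene_ids)}
        pairs = [
            (mi.values[order[x], order[y]], x, y)
            for x in part.modules[0] for y in part.modules[1]
        ]
        best = max(pairs)
        assert cand.external_genes == [best[2]]

    def test_tied_mi_broken_by_lexicographic_pair(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0)
        mi = make_mi(vals, gene_ids=["a", "b", "c", "d"])
        part = ModulePartition(mi.gene_ids, [["a", "b"], ["c", "d"]], [])
        cand = select_candidate_set(0, part, mi, 0.25)  # ceil(0.25*4)=1 of 4 tied pairs
        assert cand.external_genes == ["c"]  # pair (a, c) wins the tie

    def test_single_module_partition_gives_empty_set(self):
        mi = self._mi(4)
        part = ModulePartition(mi.gene_ids, [list(mi.gene_ids)], [])
        assert select_candidate_set(0, part, mi, 0.5).external_genes == []

    def test_candidates_disjoint_from_own_module(self):
        mi = self._mi(12, seed=7)
        part = ModulePartition(mi.gene_ids, [mi.gene_ids[:6], mi.gene_ids[6:]], [])
        cand = select_candidate_set(1, part, mi, 0.3)
        assert not set(cand.external_genes) & set(part.modules[1])


class TestBuildLinearSystem:
    def test_single_gene_module_hand_arithmetic(self):
        expr = make_expr([[1.0, 2.0, 4.0]], gene_ids=["g0"])
        part = ModulePartition(["g0"], [["g0"]], [])
        sys = build_linear_system("g0", 0, part, CandidateSet(0, []), expr)
        np.testing.assert_array_equal(sys.design, [[2.0], [4.0]])
        np.testing.assert_array_equal(sys.response, [1.0, 2.0])
        assert sys.column_gene_ids == ["g0"]

    def test_constant_target_gives_zero_response(self):
        expr = make_expr([[3.0, 3.0, 3.0, 3.0], [1.0, 2.0, 3.0, 4.0]])
        part = ModulePartition(["g0", "g1"], [["g0", "g1"]], [])
        sys = build_linear_system("g0", 0, part, CandidateSet(0, []), expr)
        np.testing.assert_array_equal(sys.response, np.zeros(3))

    def test_column_order_module_then_candidates(self):
        expr = make_expr(np.arange(20.0).reshape(4, 5))
        part = ModulePartition(["g0", "g1", "g2", "g3"], [["g0", "g1"], ["g2", "g3"]], [])
        sys = build_linear_system("g1", 0, part, CandidateSet(0, ["g3"]), expr)
        assert sys.column_gene_ids == ["g0", "g1", "g3"]
        assert sys.design.shape == (4, 3)

    def test_planted_coefficients_solve_the_system(self):
        truth = generate_truth(8, 1, 0.15, seed=4)
        expr = simulate_expression(truth, 30, noise_sd=0.0, seed=5)
        part = truth_partition(truth)
        A = truth.coefficient_matrix
        for j, gene in enumerate(truth.gene_ids):
            sys = build_linear_system(gene, 0, part, CandidateSet(0, []), expr)
            residual = sys.design @ A[j] - sys.response
            scale = max(np.abs(sys.response).max(), 1.0)
            assert np.abs(residual).max() < 1e-10 * scale

    def test_target_outside_module_rejected(self):
        expr = make_expr(np.ones((2, 4)))
        part = ModulePartition(["g0", "g1"], [["g0"], ["g1"]], [])
        with pytest.raises(InferenceError, match="not in module"):
            build_linear_system("g1", 0, part, CandidateSet(0, []), expr)


class TestSolveCoefficients:
    def test_identity_design_returns_response(self):
        sys = LinearSystem(np.eye(4), np.array([0.0, 0.0, 0.0, 1.0]), "g0",
                           ["g0", "g1", "g2", "g3"])
        coef = solve_coefficients(sys)
        np.testing.assert_allclose(coef.values, [0, 0, 0, 1], atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_qr_and_normal_equation_branches_agree(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.normal(size=(10, 5))
        d = rng.normal(size=10)
        sys = LinearSystem(H, d, "g", [f"g{i}" for i in range(5)])
        qr = solve_coefficients(sys, cond_threshold=1.0 + 1e-12)   # force QR
        ne = solve_coefficients(sys, cond_threshold=1e300)          # force normal eqs
        np.testing.assert_allclose(qr.values, ne.values, rtol=1e-8, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_least_squares_optimality_certificate(self, seed):
        rng = np.random.default_rng(100 + seed)
        H = rng.normal(size=(12, 6))
        d = rng.normal(size=12)
        sys = LinearSystem(H, d, "g", [f"g{i}" for i in range(6)])
        p = solve_coefficients(sys).values
        base = np.linalg.norm(H @ p - d)
        for _ in range(20):
            delta = rng.normal(scale=1e-3, size=6)
            assert np.linalg.norm(H @ (p + delta) - d) >= base - 1e-12

    def test_overdetermined_noiseless_recovery(self):
        rng = np.random.default_rng(9)
        H = rng.normal(size=(30, 6))
        planted = np.array([0.5, 0.0, -0.8, 0.0, 0.3, 0.0])
        sys = LinearSystem(H, H @ planted, "g", [f"g{i}" for i in range(6)])
        np.testing.assert_allclose(solve_coefficients(sys).values, planted,
                                   rtol=1e-8, atol=1e-10)

    def test_rank_deficient_design_uses_minimum_norm(self):
        H = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        sys = LinearSystem(H, H @ np.array([1.0, 0.0]), "g", ["g0", "g1"])
        coef = solve_coefficients(sys)  # cond is inf -> QR branch
        np.testing.assert_allclose(coef.values, [0.5, 0.5], atol=1e-10)

    def test_empty_design_rejected(self):
        sys = LinearSystem(np.empty((3, 0)), np.zeros(3), "g", [])
        with pytest.raises(InferenceError, match="empty design"):
            solve_coefficients(sys)


class TestBinarizeCoefficients:
    def test_theta_zero_keeps_every_nonzero_non_self(self):
        coef = CoefficientVector(np.array([0.2, 0.0, -0.1]), "b", ["a", "b", "c"])
        assert binarize_coefficients(coef, 0.0) == {("a", "b"), ("c", "b")}

    def test_magnitude_rule_keeps_large_negative(self):
        coef = CoefficientVector(np.array([0.3, -0.5]), "t", ["a", "b"])
        assert binarize_coefficients(coef, 0.4) == {("b", "t")}

    def test_self_edge_always_excluded(self):
        coef = CoefficientVector(np.array([9.0]), "a", ["a"])
        assert binarize_coefficients(coef, 0.0) == set()

    def test_edge_sets_nested_along_theta_grid(self, rng):
        coef = CoefficientVector(rng.normal(scale=0.2, size=20), "t",
                                 [f"g{i}" for i in range(20)])
        grid = [round(0.01 * k, 2) for k in range(41)]
        previous = None
        for theta in grid:
            edges = binarize_coefficients(coef, theta)
            if previous is not None:
                assert edges <= previous
            previous = edges


class TestInferModule:
    def test_single_constant_gene_module_empty_fragment(self):
        expr = make_expr([[2.0, 2.0, 2.0, 2.0]], gene_ids=["g0"])
        part = ModulePartition(["g0"], [["g0"]], [])
        frag = infer_module(0, part, CandidateSet(0, []), expr, RunConfig())
        assert frag.weights == {}

    def test_one_coefficient_vector_per_module_gene(self):
        truth = generate_truth(9, 3, 0.1, seed=2)
        expr = simulate_expression(truth, 25, seed=3)
        part = truth_partition(truth)
        frag = infer_module(1, part, CandidateSet(1, []), expr, RunConfig(theta=0.0))
        targets = {tgt for _, tgt in frag.weights}
        assert targets == set(part.modules[1])

    def test_planted_module_structure_recovered_at_half_dead_zone(self):
        # 5-gene single-module system, noiseless: edges recovered exactly
        truth = generate_truth(5, 1, 0.2, seed=11)
        expr = simulate_expression(truth, 60, noise_sd=0.0, seed=12)
        part = truth_partition(truth)
        frag = infer_module(0, part, CandidateSet(0, []), expr, RunConfig(theta=0.1))
        assert frag.binary_edges == truth.edges
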