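"""Enzyme-cost optimization: exact operations, oracle agreement, and the
structural invariants of the optimum."""

import numpy as np
import pytest

import metcomp as mc
from metcomp import ParameterDomainError, SolverOptions
from conftest import single_cell_brute_force_optimum


class TestAsymmetryAndCost:
    @pytest.mark.parametrize(
        "e1, e2, expected",
        [(1.0, 1.0, 0.0), (0.7, 0.0, 1.0), (1.0, 3.0, -0.5), (0.0, 0.0, 0.0)],
    )
    def test_enzyme_asymmetry(self, e1, e2, expected):
        assert mc.enzyme_asymmetry(e1, e2) == pytest.approx(expected)

    def test_asymmetry_rejects_negative(self):
        with pytest.raises(ParameterDomainError):
            mc.enzyme_asymmetry(-0.1, 1.0)

    @pytest.mark.parametrize(
        "enzymes, fractions, expected",
        [
            ([[1, 1, 1], [0, 1, 1]], (0.5, 0.5), 2.5),
            ([[0, 0, 0], [0, 0, 0]], (0.5, 0.5), 0.0),
            ([[1, 2, 3], [9, 9, 9]], (1.0, 0.0), 6.0),
        ],
    )
    def test_total_cost(self, enzymes, fractions, expected):
        assert mc.total_cost(enzymes, fractions) == pytest.approx(expected)


class TestOracleAgreement:
    def test_decoupled_cells_match_brute_force_grid_search(self, quick_options):
        """With D_X = D_P = 0 the two cells are independent single-cell
        problems; the optimizer must agree with an exhaustive refined grid
        search over enzyme space (independent root-finding oracle) and
        allocate symmetrically."""
        model = mc.default_consortium(inv_K_I=10.0, D_X=0.0, D_P=0.0)
        sol = mc.minimize_enzyme_cost(model, quick_options)
        assert sol.converged
        oracle = single_cell_brute_force_optimum(model.kinetics, model.substrate_conc)
        # Eq. 6 weights each cell by n_i = 1/2, so C equals one cell's total
        assert sol.cost == pytest.approx(oracle, rel=0.02)
        assert np.max(np.abs(sol.asymmetries)) < 1e-3


class TestOptimalAllocationStructure:
    def test_weak_inhibition_is_symmetric(self, weak_inhibition_model, quick_options):
        sol = mc.minimize_enzyme_cost(weak_inhibition_model, quick_options)
        assert sol.converged
        assert np.max(np.abs(sol.asymmetries)) < 1e-3

    def test_strong_inhibition_splits_first_enzyme(self, strong_inhibition_model, quick_options):
        """A_S jumps to exactly 1 (cell 2 loses E_S entirely), with the
        downstream enzymes enriched in the complementary directions."""
        sol = mc.minimize_enzyme_cost(strong_inhibition_model, quick_options)
        assert sol.converged
        A_S, A_X, A_P = sol.asymmetries
        assert A_S == pytest.approx(1.0, abs=1e-3)
        assert A_X < 0 and A_P > 0
        assert sol.enzymes[1, 0] == 0.0

    def test_demand_saturation(self, strong_inhibition_model, quick_options):
        """Excess production is never cost-optimal: every consumption flux
        sits exactly on its demand bound."""
        for model in (strong_inhibition_model,
                      mc.default_consortium(inv_K_I=0.1, D_X=1.0, D_P=1.0)):
            sol = mc.minimize_enzyme_cost(model, quick_options)
            np.testing.assert_allclose(sol.fluxes.V_P, model.demands, rtol=1e-6)
            assert sol.active_demands.all()

    def test_mirror_symmetry(self, quick_options):
        """Swapping the two cells' demand labels mirrors the solution:
        identical cost, negated asymmetries."""
        base = dict(inv_K_I=10.0, D_X=10.0, D_P=1.0)
        m_fwd = mc.default_consortium(demands=(1.3, 0.7), **base)
        m_rev = mc.default_consortium(demands=(0.7, 1.3), **base)
        opts = SolverOptions(n_starts=8, seed=5, symmetry_restriction="none")
        s_fwd = mc.minimize_enzyme_cost(m_fwd, opts)
        s_rev = mc.minimize_enzyme_cost(m_rev, opts)
        assert s_fwd.cost == pytest.approx(s_rev.cost, rel=1e-5)
        np.testing.assert_allclose(s_fwd.asymmetries, -s_rev.asymmetries, atol=1e-3)


class TestScalingLaw:
    def test_cost_linear_in_demands_at_non_exchanging_optimum(self, quick_options):
        """Where the optimum exchanges nothing (weak inhibition), scaling
        all demands by lambda scales C by exactly lambda and leaves the
        asymmetries at zero. (With nonzero optimal exchange the law holds
        only approximately: exchange fluxes pin concentration gaps
        proportional to demand while saturation is not homogeneous.)"""
        base = mc.default_consortium(inv_K_I=0.1, D_X=3.0, D_P=3.0)
        ref = mc.minimize_enzyme_cost(base, quick_options)
        for lam in (0.5, 2.0):
            scaled = mc.default_consortium(inv_K_I=0.1, D_X=3.0, D_P=3.0,
                                           demands=(lam, lam))
            sol = mc.minimize_enzyme_cost(scaled, quick_options)
            assert sol.cost == pytest.approx(lam * ref.cost, rel=1e-4)
            assert np.max(np.abs(sol.asymmetries)) < 1e-3

    def test_sandwich_inequalities(self, strong_inhibition_model, quick_options):
        """Constrained costs bound the unconstrained one from above, and
        superlinearity of C in the demands bounds it from below by the
        doubled half-demand cost."""
        model = strong_inhibition_model
        free = mc.minimize_enzyme_cost(model, quick_options)
        sym = mc.minimize_with_symmetry_constraint(model, "force_symmetric", quick_options)
        split = mc.minimize_with_symmetry_constraint(model, "force_split", quick_options)
        assert sym.cost >= free.cost - 1e-6
        assert split.cost >= free.cost - 1e-6
        half = mc.default_consortium(inv_K_I=10.0, D_X=10.0, D_P=0.1, demands=(0.5, 0.5))
        s_half = mc.minimize_enzyme_cost(half, quick_options)
        assert free.cost >= 2 * s_half.cost - 1e-6


class TestSymmetryConstraints:
    def test_split_beats_symmetric_at_high_DX_low_DP(self, strong_inhibition_model, quick_options):
        sym = mc.minimize_with_symmetry_constraint(
            strong_inhibition_model, "force_symmetric", quick_options)
        split = mc.minimize_with_symmetry_constraint(
            strong_inhibition_model, "force_split", quick_options)
        assert split.cost < sym.cost

    @pytest.mark.parametrize("D", [0.02, 0.3])
    def test_symmetric_beats_split_at_low_permeabilities(self, D, quick_options):
        """When the metabolites barely diffuse, forcing the split is costly
        -- or outright infeasible once D (ΔX)_max falls below the exchange
        flux a split requires."""
        model = mc.default_consortium(inv_K_I=10.0, D_X=D, D_P=D)
        sym = mc.minimize_with_symmetry_constraint(model, "force_symmetric", quick_options)
        split = mc.minimize_with_symmetry_constraint(model, "force_split", quick_options)
        assert sym.converged
        assert (not split.converged) or split.cost > sym.cost

    def test_force_symmetric_yields_equal_cells(self, strong_inhibition_model, quick_options):
        sol = mc.minimize_with_symmetry_constraint(
            strong_inhibition_model, "force_symmetric", quick_options)
        np.testing.assert_allclose(sol.enzymes[0], sol.enzymes[1], rtol=1e-5, atol=1e-8)


class TestDualFormulation:
    def test_budget_C_star_achieves_lambda_one(self, strong_inhibition_model, quick_options):
        primal = mc.minimize_enzyme_cost(strong_inhibition_model, quick_options)
        dual = mc.maximize_flux_under_budget(strong_inhibition_model, primal.cost, quick_options)
        assert dual.converged
        assert dual.metadata["lambda"] == pytest.approx(1.0, abs=5e-3)

    def test_doubled_budget_doubles_flux_at_non_exchanging_optimum(self, quick_options):
        model = mc.default_consortium(inv_K_I=0.1, D_X=3.0, D_P=3.0)
        primal = mc.minimize_enzyme_cost(model, quick_options)
        dual = mc.maximize_flux_under_budget(model, 2 * primal.cost, quick_options)
        assert dual.metadata["lambda"] == pytest.approx(2.0, rel=1e-3)

    def test_zero_budget_trivial(self, strong_inhibition_model, quick_options):
        dual = mc.maximize_flux_under_budget(strong_inhibition_model, 0.0, quick_options)
        assert dual.metadata["lambda"] == 0.0 and dual.converged


class TestMultistartAndContinuation:
    def test_same_seed_reproduces_solution(self, strong_inhibition_model):
        spec = {"kind": "min_cost", "mode": "none", "restriction": "A_S_nonnegative"}
        a = mc.multistart(strong_inhibition_model, spec, SolverOptions(n_starts=4, seed=9))
        b = mc.multistart(strong_inhibition_model, spec, SolverOptions(n_starts=4, seed=9))
        assert a.cost == b.cost
        np.testing.assert_array_equal(a.enzymes_raw, b.enzymes_raw)
        assert a.n_starts_used == b.n_starts_used

    def test_infeasible_host_demand_reported_not_raised(self, quick_options):
        model = mc.default_consortium(D_P=0.0, host_demand=1.0)
        sol = mc.minimize_enzyme_cost(model, quick_options)
        assert not sol.converged
        assert "infeasible" in sol.metadata

    def test_constant_path_constant_cost(self, strong_inhibition_model, quick_options):
        models = [strong_inhibition_model] * 3
        sols = mc.continuation_sweep(models, quick_options)
        costs = [s.cost for s in sols]
        assert max(costs) - min(costs) < 1e-6 * costs[0]

    def test_warm_start_not_worse_than_cold(self, quick_options):
        """Along a D_X path crossing the regime transition the warm-started
        sweep must match independent cold multistarts, while the cost stays
        continuous and A_S jumps between 0 and 1."""
        DXs = np.geomspace(0.2, 20.0, 6)
        models = [mc.default_consortium(inv_K_I=10.0, D_X=d, D_P=1.0) for d in DXs]
        sweep = mc.continuation_sweep(models, quick_options)
        A = [s.asymmetries[0] for s in sweep]
        costs = [s.cost for s in sweep]
        for model, warm in zip(models, sweep):
            cold = mc.minimize_enzyme_cost(model, SolverOptions(n_starts=12, seed=77))
            assert warm.cost <= cold.cost * (1 + 1e-4)
        # both regimes are visited and A_S is two-valued
        assert min(A) < 1e-3 and max(A) > 1 - 1e-3
        assert all(a < 1e-3 or a > 1 - 1e-3 for a in A)
        # cost varies smoothly (< 35% between neighbours on this coarse path)
        rel = np.abs(np.diff(costs)) / costs[:-1]
        assert rel.max() < 0.35
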