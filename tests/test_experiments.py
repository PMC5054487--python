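"""Phase-diagram machinery, regime classification, sweeps, sensitivity,
and the extended multi-intermediate chain."""

import numpy as np
import pytest

import metcomp as mc
from metcomp import ParameterDomainError, SolverOptions
from metcomp.experiments import classify_regime, split_point


def solve(model, seed=21, n_starts=6):
    return mc.minimize_enzyme_cost(model, SolverOptions(n_starts=n_starts, seed=seed))


class TestClassifyRegime:
    def test_neutralist_at_weak_inhibition(self, weak_inhibition_model, quick_options):
        sol = mc.minimize_enzyme_cost(weak_inhibition_model, quick_options)
        assert classify_regime(sol) == "neutralist"

    def test_cheater_when_product_cannot_return(self, quick_options):
        # X flows to cell 2 while P cannot cross the membrane at all
        sol = solve(mc.default_consortium(inv_K_I=10.0, D_X=10.0, D_P=0.0))
        assert sol.asymmetries[0] == pytest.approx(1.0, abs=1e-3)
        assert classify_regime(sol) == "cheater"

    def test_complementation_when_product_shuttles_back(self, strong_inhibition_model, quick_options):
        sol = mc.minimize_enzyme_cost(strong_inhibition_model, quick_options)
        assert sol.fluxes.U_P[0] < 0  # P flows from cell 2 into cell 1
        assert classify_regime(sol) == "complementation"

    def test_labels_invariant_under_relabeling(self, quick_options):
        """The mirrored solution (A_S = -1 branch) gets the same label."""
        model = mc.default_consortium(inv_K_I=10.0, D_X=10.0, D_P=0.1)
        opts = SolverOptions(n_starts=10, seed=3, symmetry_restriction="none")
        sol = mc.minimize_enzyme_cost(model, opts)
        assert abs(sol.asymmetries[0]) == pytest.approx(1.0, abs=1e-3)
        assert classify_regime(sol) == "complementation"

    def test_refuses_unconverged(self, quick_options):
        sol = mc.minimize_enzyme_cost(
            mc.default_consortium(D_P=0.0, host_demand=1.0), quick_options)
        with pytest.raises(ParameterDomainError):
            classify_regime(sol)


class TestSplitPoint:
    def _fake_solution(self, e1, e2):
        import metcomp.optimize as opt

        E = np.vstack([e1, e2]).astype(float)
        m = E.shape[1] - 2
        state = mc.CompartmentState(np.ones((2, m)), np.ones(2), np.ones(m), 1.0)
        model = mc.default_consortium(chain_length=m).with_enzymes(E)
        fluxes = mc.compute_fluxes(model, state)
        return opt.AllocationSolution(
            enzymes=E, enzymes_raw=E, state=state, cost=float(E.sum() / 2),
            asymmetries=np.zeros(m + 2), both_absent=np.zeros(m + 2, bool),
            fluxes=fluxes, converged=True, n_starts_used=1, seed=0,
            active_demands=np.ones(2, bool),
        )

    def test_hand_built_partition(self):
        sol = self._fake_solution([1, 1, 0, 0, 0, 0, 0.001], [0, 0, 1, 1, 1, 1, 1])
        assert split_point(sol) == 2

    def test_symmetric_has_no_split(self):
        sol = self._fake_solution([1, 1, 1], [1, 1, 1])
        assert split_point(sol) is None

    def test_partial_overlap_has_no_split(self):
        sol = self._fake_solution([1, 1, 1, 0, 0, 0, 1], [0, 1, 1, 1, 1, 1, 1])
        assert split_point(sol) is None


class TestExtendedChain:
    @pytest.mark.parametrize("perm", [1, 3, 5])
    def test_pathway_splits_at_permeable_intermediate(self, perm):
        """m = 5 chain, K_eq = 4/3, strong inhibition, [S] = 20: with only P
        and X_perm permeable, the optimal allocation splits the chain
        exactly at the permeable intermediate."""
        sol, idx = mc.extended_split_experiment(
            perm, options=SolverOptions(n_starts=12, seed=31))
        assert sol.converged
        assert idx == perm
        assert sol.asymmetries[0] == pytest.approx(1.0, abs=1e-3)

    def test_no_permeable_intermediate_no_split(self):
        """With every intermediate impermeable (only P diffuses) the two
        cells cannot share intermediates and allocate symmetrically."""
        model = mc.extended_consortium(1, D_perm=15.0)
        D = model.permeabilities.copy()
        D[0] = 1e-3  # revoke the one permeable intermediate
        model = mc.extended_consortium(1, permeabilities=D)
        sol, idx = mc.extended_split_experiment(1, model=model,
                                                options=SolverOptions(n_starts=10, seed=32))
        assert sol.converged
        assert idx is None
        assert np.max(np.abs(sol.asymmetries)) < 1e-3

    def test_generic_chain_matches_dedicated_two_reaction_implementation(self):
        """On random m = 1 parameter sets the generalized chain machinery
        must agree with an independently coded two-reaction reduction."""
        from scipy.optimize import minimize as scipy_min

        rng = np.random.default_rng(7)
        for _ in range(5):
            S = rng.uniform(5, 15)
            invKI = rng.uniform(0.5, 5)
            DX, DP = rng.uniform(0.2, 5, 2)
            Keq = rng.uniform(0.8, 1.3)
            model = mc.default_consortium(substrate_conc=S, inv_K_I=invKI,
                                          D_X=DX, D_P=DP, K_eq=Keq)
            sol = solve(model, seed=41, n_starts=8)

            # dedicated m=1 oracle: same mathematical problem, coded flat
            def cost2(z):
                X = np.exp(z[0:2]); P = np.exp(z[2:4]); v = z[4:6]
                UX = DX * (X - X.mean()); UP = DP * (P - P.mean())
                VX = v + UP; VS = VX + UX
                effS = (1 / (1 + P * invKI)) * (S - X / Keq) / (1 + S + X)
                effX = (X - P / Keq) / (1 + X + P)
                effP = P / (P + 1)
                if (np.any(effS <= 0) or np.any(effX <= 0) or np.any(VS < -1e-9)
                        or np.any(VX < -1e-9) or np.any(v < 1 - 1e-12)):
                    return 1e9
                return 0.5 * float((VS / effS + VX / effX + v / effP).sum())

            best = np.inf
            for _ in range(40):
                z0 = np.concatenate([np.log(rng.uniform(0.05, 0.8 * Keq * S, 2)),
                                     np.log(rng.uniform(0.02, 0.5 * Keq * Keq * S, 2)),
                                     [1.0, 1.0]])
                r = scipy_min(cost2, z0, method="Nelder-Mead",
                              options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-10})
                if r.fun < best:
                    best = r.fun
            assert sol.cost <= best * 1.02


class TestSweeps:
    def test_zero_demand_asymmetry_reproduces_base_case(self):
        model = mc.default_consortium(inv_K_I=10.0, D_X=10.0, D_P=1.0)
        base = solve(model, seed=51, n_starts=8)
        res = mc.demand_and_population_sweeps(model, "rho_J", [0.0],
                                              SolverOptions(n_starts=8, seed=51))
        assert res.records[0]["cost"] == pytest.approx(base.cost, rel=1e-5)
        assert abs(res.records[0]["A_S"]) == pytest.approx(abs(base.asymmetries[0]), abs=1e-3)

    def test_large_demand_asymmetry_reverses_the_split(self):
        """Strong inhibition plus strongly unequal demands: complete
        splitting with the reversed orientation [E_S,1] = [E_X,2] = 0."""
        model = mc.default_consortium(inv_K_I=30.0, D_X=10.0, D_P=1.0)
        res = mc.demand_and_population_sweeps(model, "rho_J", [0.9],
                                              SolverOptions(n_starts=8, seed=52))
        rec = res.records[0]
        assert rec["converged"]
        assert rec["E_S1_frac"] <= 1e-6 and rec["E_X2_frac"] <= 1e-6
        assert rec["A_S"] == pytest.approx(-1.0, abs=1e-3)

    def test_cost_increases_with_host_demand(self):
        model = mc.default_consortium(inv_K_I=10.0, D_X=10.0, D_P=1.0)
        res = mc.demand_and_population_sweeps(model, "J_P_0", [0.0, 0.5, 1.0],
                                              SolverOptions(n_starts=6, seed=53))
        costs = [r["cost"] for r in res.records]
        assert costs[0] < costs[1] < costs[2]

    def test_host_demand_requires_permeable_product(self):
        model = mc.default_consortium(inv_K_I=1.0, D_X=1.0, D_P=0.0)
        res = mc.demand_and_population_sweeps(model, "J_P_0", [0.0, 0.5],
                                              SolverOptions(n_starts=4, seed=54))
        assert res.records[0]["converged"]
        assert not res.records[1]["converged"]


class TestPhaseDiagram:
    def test_small_grid_structure(self):
        """A coarse 3x3 grid at weak and strong inhibition shows the
        symmetric slice, a split region at high D_X / low D_P, and
        continuity of cost between neighbours within a regime."""
        D = np.array([0.1, 1.0, 10.0])
        result = mc.phase_diagram(D_X_values=D, D_P_values=D,
                                  inv_K_I_values=[0.1, 10.0],
                                  options=SolverOptions(n_starts=6, seed=61))
        df = result.to_frame()
        assert len(df) == 18
        weak = df[df.inv_K_I == 0.1]
        assert (weak[["A_S", "A_X", "A_P"]].abs().to_numpy() < 1e-3).all()
        assert set(weak.regime) == {"neutralist"}
        strong = df[(df.inv_K_I == 10.0) & (df.D_X == 10.0) & (df.D_P == 0.1)]
        assert strong.iloc[0]["A_S"] == pytest.approx(1.0, abs=1e-3)

    def test_records_include_failures_without_raising(self):
        # host demand with D_P = 0 is infeasible; the sweep must keep going
        template = mc.default_consortium(host_demand=0.5)
        result = mc.phase_diagram(model_template=template,
                                  D_X_values=[1.0], D_P_values=[0.0, 1.0],
                                  inv_K_I_values=[1.0],
                                  options=SolverOptions(n_starts=4, seed=62))
        df = result.to_frame()
        assert (~df.converged).sum() == 1 and df.converged.sum() == 1


class TestSensitivity:
    def test_degenerate_constant_asymmetry_gives_zero_covariance(self):
        """Deep in the symmetric regime a small perturbation never flips
        the optimum, so A_S is constant and every covariance vanishes."""
        model = mc.default_consortium(inv_K_I=0.1, D_X=1.0, D_P=1.0)
        res = mc.sensitivity_analysis(model, rel_magnitude=0.05, n_samples=12,
                                      seed=71, options=SolverOptions(n_starts=4))
        assert res.n_samples + res.n_excluded == 12
        # A_S is zero up to solver round-off (~1e-6), so every covariance
        # sits at that noise floor -- orders of magnitude below the ~0.1
        # covariances seen at the regime boundary
        assert all(abs(c) < 1e-4 for c in res.covariance.values())
        assert res.to_frame().shape[0] == len(res.parameters)

    def test_reproducible_given_seed(self):
        model = mc.default_consortium(inv_K_I=10.0, D_X=2.0, D_P=1.0)
        a = mc.sensitivity_analysis(model, n_samples=6, seed=72,
                                    options=SolverOptions(n_starts=4))
        b = mc.sensitivity_analysis(model, n_samples=6, seed=72,
                                    options=SolverOptions(n_starts=4))
        assert a.covariance == b.covariance
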