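"""Enzyme-cost minimization for the two-population consortium.

The optimization problem: minimize the population-weighted total enzyme
concentration

    C = sum_i sum_alpha n_i [E_alpha,i]

subject to steady state of every balance equation, the demand constraints
V_P,i >= J_P,i, the host demand (met through the extracellular product
balance), and nonnegativity of enzymes and concentrations.

Formulation
-----------
Rather than treating the steady-state balances as nonlinear equality
constraints, they are eliminated analytically:

* exchange closure fixes the extracellular concentrations,
  [X_k]_out = n1 [X_k,1] + n2 [X_k,2] and
  [P]_out = n1 [P_1] + n2 [P_2] - J_P,0 / D_P;
* the intracellular balances determine every synthesis flux by
  back-substitution down the chain from the consumption fluxes;
* each enzyme concentration is then flux / (per-unit-enzyme rate).

What remains is a small NLP over the logarithms of the intracellular
metabolite concentrations plus the two consumption fluxes, with inequality
constraints only. The search is restricted to forward-operating solutions
(positive thermodynamic driving force and nonnegative flux on every
synthesis step): operating a step backwards consumes enzyme without
contributing to demand and is never cost-optimal. Steady state holds
exactly by construction and is re-verified on every accepted solution
through the independent :func:`metcomp.model.balance_residuals` path.

The cost landscape has multiple local optima (symmetric and split
branches); :func:`multistart` runs a seeded portfolio of random and
structured starting points and keeps the best feasible local optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import InfeasibleModelError, ParameterDomainError
from .kinetics import unit_consumption_rate
from .model import (
    CompartmentState,
    ConsortiumModel,
    SteadyStateSolution,
    compute_fluxes,
)

__all__ = [
    "SolverOptions",
    "AllocationSolution",
    "enzyme_asymmetry",
    "total_cost",
    "minimize_enzyme_cost",
    "minimize_with_symmetry_constraint",
    "maximize_flux_under_budget",
    "multistart",
    "continuation_sweep",
]

#: lower bound on the thermodynamic driving force of an operating step
EPS_EFF = 1e-9
#: log-concentration bounds
LOG_LO, LOG_HI = np.log(1e-9), np.log(1e4)
#: enzymes below this fraction of the total cost are reported as exact zeros
ZERO_ENZYME_FRACTION = 1e-6


@dataclass
class SolverOptions:
    """Options controlling the multistart local solver.

    ``n_starts`` random initializations are drawn log-uniformly (each start
    respects the forward-operating restriction); a deterministic portfolio
    of structured starts (symmetric profile plus one split profile per
    possible breaking point) is always added. ``symmetry_restriction``
    breaks the +/- degeneracy of asymmetric solutions by restricting to
    [E_S,1] >= [E_S,2] (i.e. A_S >= 0).
    """

    n_starts: int = 24
    seed: int = 0
    constraint_tolerance: float = 1e-7
    optimality_tolerance: float = 1e-12
    symmetry_restriction: str = "A_S_nonnegative"  # or "none"
    warm_start: "AllocationSolution | None" = None
    max_iter: int = 400
    n_starts_sweep: int = 6  # random starts per point inside continuation sweeps
    boundary_cost_rtol: float = 1e-5  # regime-boundary tie tolerance

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ParameterDomainError("n_starts must be >= 1")
        if self.constraint_tolerance <= 0 or self.optimality_tolerance <= 0:
            raise ParameterDomainError("tolerances must be > 0")
        if self.symmetry_restriction not in ("none", "A_S_nonnegative"):
            raise ParameterDomainError("symmetry_restriction must be 'none' or 'A_S_nonnegative'")


@dataclass
class AllocationSolution:
    """Result of one enzyme-allocation optimization.

    ``enzymes`` is the (2, m+2) matrix after exact-zero thresholding (raw
    values in ``enzymes_raw``); ``asymmetries`` holds A_alpha per enzyme in
    the canonical ordering; ``fluxes`` carries all fluxes and the balance
    residual norm recomputed through the rate laws.
    """

    enzymes: np.ndarray
    enzymes_raw: np.ndarray
    state: CompartmentState
    cost: float
    asymmetries: np.ndarray
    both_absent: np.ndarray  # enzymes absent from both cells (A defined as 0)
    fluxes: SteadyStateSolution
    converged: bool
    n_starts_used: int
    seed: int
    active_demands: np.ndarray  # which V_P,i >= J_P,i constraints are tight
    metadata: dict = field(default_factory=dict)

    @property
    def residual_norm(self) -> float:
        return self.fluxes.residual_norm


def enzyme_asymmetry(e1: float, e2: float) -> float:
    """A = (e1 - e2) / (e1 + e2); zero (by convention) when both vanish."""
    if e1 < 0 or e2 < 0:
        raise ParameterDomainError("enzyme concentrations must be >= 0")
    if e1 + e2 == 0:
        return 0.0
    return (e1 - e2) / (e1 + e2)


def total_cost(enzymes, fractions) -> float:
    """Population-weighted total enzyme concentration (the objective C)."""
    enzymes = np.atleast_2d(np.asarray(enzymes, dtype=float))
    n = np.asarray(fractions, dtype=float)
    if abs(n.sum() - 1.0) > 1e-9:
        raise ParameterDomainError("population fractions must sum to 1")
    return float(n @ enzymes.sum(axis=1))


# ---------------------------------------------------------------------------
# reduced problem
# ---------------------------------------------------------------------------


class _ReducedProblem:
    """Physics and constraint assembly for the reduced NLP.

    Variables: z = [log c (2*(m+1), row-major by cell) | extras], where
    extras are the consumption fluxes (v1, v2) for cost minimization or the
    demand-scaling factor lambda for flux maximization.
    """

    def __init__(self, model: ConsortiumModel, objective="min_cost", mode="none",
                 budget=None, restriction="none"):
        self.model = model
        self.objective = objective
        self.mode = mode
        self.budget = budget
        self.restriction = restriction
        self.m = model.chain_length
        self.nC = self.m + 1
        self.n = model.fractions
        self.J = model.demands
        self.J0 = model.host_demand
        self.DX = model.D_X
        self.DP = model.D_P
        if self.J0 > 0 and self.DP == 0:
            raise InfeasibleModelError(
                "host demand J_P,0 > 0 requires a permeable product (D_P > 0)"
            )
        self.n_extras = 1 if objective == "max_flux" else 2
        self.n_vars = 2 * self.nC + self.n_extras
        self.kin = model.kinetics
        # vectorized kinetic constants over the m+1 synthesis reactions
        syn = model.kinetics[: self.m + 1]
        self._kcat = np.array([k.k_cat for k in syn])
        self._KMf = np.array([k.K_M_fwd for k in syn])
        self._KMr = np.array([k.K_M_rev for k in syn])
        self._Keq = np.array([k.K_eq for k in syn])
        self._inh_mode = syn[0].inhibition_mode
        self._invKI = syn[0].inv_K_I
        self._kin_cons = model.kinetics[self.m + 1]
        self._hinge_s = 0.1 * max(float(self.J.sum()) + self.J0, 1.0)

    # -- physics ---------------------------------------------------------
    def physics(self, z):
        m, nC = self.m, self.nC
        conc = np.exp(z[: 2 * nC]).reshape(2, nC)
        X, P = conc[:, :m], conc[:, m]
        if self.objective == "max_flux":
            lam = z[-1]
            v = lam * self.J
            J0 = lam * self.J0
        else:
            lam = None
            v = z[2 * nC : 2 * nC + 2]
            J0 = self.J0

        X_out = np.where(self.DX > 0, self.n @ X, 0.0)
        U_X = np.where(self.DX > 0, self.DX * (X - X_out), 0.0)
        if self.DP > 0:
            P_out = float(self.n @ P - J0 / self.DP)
            U_P = self.DP * (P - P_out)
        else:
            P_out = 0.0
            U_P = np.zeros(2)

        # back-substitution of the chain balances: V_{j-1} = V_j + U_{X_j}
        V = np.empty((2, m + 1))
        V[:, m] = v + U_P
        if m > 0:
            V[:, :m] = V[:, m][:, None] + np.cumsum(U_X[:, ::-1], axis=1)[:, ::-1]

        # per-unit-enzyme synthesis rates, vectorized over reactions
        sub = np.hstack([np.full((2, 1), self.model.substrate_conc), conc[:, :m]])
        drive = (sub - conc / self._Keq) / self._KMf
        denom = 1.0 + sub / self._KMf + conc / self._KMr
        pref = np.broadcast_to(self._kcat, (2, m + 1)).copy()
        if self._inh_mode == "uncompetitive":
            pref[:, 0] = self._kcat[0] / (1.0 + P * self._invKI)
        elif self._inh_mode == "competitive":
            denom[:, 0] = denom[:, 0] + P * self._invKI
        eff = pref * drive / denom
        eff_P = unit_consumption_rate(self._kin_cons, P)

        with np.errstate(divide="ignore", invalid="ignore"):
            E_syn = V / eff
            E_P = v / eff_P
        E = np.hstack([E_syn, E_P[:, None]])
        return dict(conc=conc, X=X, P=P, v=v, lam=lam, X_out=X_out, P_out=P_out,
                    U_X=U_X, U_P=U_P, V=V, eff=eff, eff_P=eff_P, E=E)

    def cost(self, ph) -> float:
        """Cost as seen by the solver.

        Near any candidate optimum this IS the true cost
        sum_i n_i sum_alpha V/eff = sum n_i [E_alpha,i], and it is smooth
        through V = 0, so split optima (where one cell's head flux
        vanishes) are ordinary KKT points. Far from optima two guards keep
        it bounded below so the line search cannot escape to -inf through
        transiently infeasible regions: the efficacy denominator is
        clamped at 1e-3 (no optimum can sit below that: an enzyme with
        eff < 1e-3 carrying a demand-scale flux would alone cost ~1e3
        demand units), and negative fluxes enter through a C^1
        exponential hinge that saturates at -s instead of growing
        linearly."""
        V = ph["V"].copy()
        neg = V < 0
        if np.any(neg):
            V[neg] = self._hinge_s * np.expm1(V[neg] / self._hinge_s)
        terms = V / np.maximum(ph["eff"], 1e-3)
        c = float(self.n @ (terms.sum(axis=1) + ph["v"] / ph["eff_P"]))
        return c if np.isfinite(c) else 1e12

    def raw_cost(self, z) -> float:
        """True cost at a (feasible) point."""
        ph = self.physics(z)
        return float(self.n @ np.maximum(ph["E"], 0.0).sum(axis=1))

    def objective_fun(self, z) -> float:
        ph = self.physics(z)
        if self.objective == "max_flux":
            return -ph["lam"]
        return self.cost(ph)

    def ineq(self, z):
        ph = self.physics(z)
        parts = [ph["eff"].ravel() - EPS_EFF, ph["V"].ravel()]
        if self.DP > 0:
            parts.append([ph["P_out"]])
        if self.restriction == "A_S_nonnegative":
            parts.append([ph["E"][0, 0] - ph["E"][1, 0]])
        if self.objective == "max_flux":
            # relative scaling keeps the feasibility tolerance meaningful
            parts.append([(self.budget - self.cost(ph)) / max(self.budget, 1.0)])
        out = np.concatenate([np.atleast_1d(p) for p in parts])
        return np.where(np.isfinite(out), out, -1e6)

    def eq(self, z):
        ph = self.physics(z)
        if self.mode == "force_symmetric":
            return ph["E"][0] - ph["E"][1]
        if self.mode == "force_split":
            return np.array([ph["V"][1, 0]])
        return np.zeros(0)

    # -- variable helpers ------------------------------------------------
    def bounds(self):
        """Box bounds: each species is capped slightly above its full
        running-equilibrium level (every feasible point satisfies
        [B_r] < K_eq,r [A_r] step by step, so the cap excludes no feasible
        point while removing the far-out regions where the cost ratio
        misbehaves)."""
        eq = self.equilibrium_cascade()
        ub = np.minimum(np.log(1.05 * eq), LOG_HI)
        b = [(LOG_LO, float(u)) for u in ub] * 2
        if self.objective == "max_flux":
            b.append((0.0, 1e6))
        else:
            b += [(self.J[0], 1e6), (self.J[1], 1e6)]
        return b

    def pack_start(self, conc):
        hi = np.minimum(1.04 * self.equilibrium_cascade(), 0.95e4)
        logc = np.log(np.clip(conc, 1.05e-9, hi[None, :])).ravel()
        if self.objective == "max_flux":
            return np.concatenate([logc, [1.0]])
        return np.concatenate([logc, np.maximum(self.J, 1e-6)])

    def equilibrium_cascade(self):
        """Concentration scale of each species at full equilibrium with S."""
        if not hasattr(self, "_eq_cache"):
            eq = np.zeros(self.nC)
            level = self.model.substrate_conc
            for r in range(self.m + 1):
                level = level * self.kin[r].K_eq
                eq[r] = level
            self._eq_cache = eq
        return self._eq_cache

    def _gap_caps(self, cbar):
        """Largest sensible relative inter-cell concentration gap per
        species: exchange fluxes scale as D * n2 * (c1 - c2), so permeable
        species must stay nearly equal across cells for the chain fluxes to
        remain of order of the demand."""
        D = np.concatenate([self.DX, [self.DP]])
        Jref = max(float(self.J.sum()) + self.J0, 1e-6)
        n2 = max(self.n.min(), 1e-6)
        with np.errstate(divide="ignore"):
            cap = 2.0 * Jref / (np.maximum(D, 1e-12) * np.maximum(cbar, 1e-12) * n2)
        # 0.35 keeps every start strictly below the running equilibrium so
        # the feasibility clip never cascades onto neighbouring species
        return np.minimum(0.35, cap)

    def _clip_cascade(self, conc):
        """Clip each cell's profile below the running equilibrium so every
        step starts with positive thermodynamic driving force."""
        out = conc.copy()
        for i in range(2):
            prev = self.model.substrate_conc
            for r in range(self.nC):
                out[i, r] = min(out[i, r], 0.85 * self.kin[r].K_eq * prev)
                out[i, r] = max(out[i, r], 1e-8)
                prev = out[i, r]
        return out

    def random_start(self, rng):
        """Shared random cascade plus per-species asymmetry, with the gap of
        each species capped by its permeability."""
        cbar = np.zeros(self.nC)
        prev = self.model.substrate_conc
        for r in range(self.nC):
            ratio = np.exp(rng.uniform(np.log(5e-3), np.log(0.8)))
            cbar[r] = prev * self.kin[r].K_eq * ratio
            prev = cbar[r]
        g = self._gap_caps(cbar) * rng.uniform(-1.0, 1.0, self.nC)
        conc = np.vstack([cbar * (1 + g), cbar * (1 - g)])
        return self.pack_start(self._clip_cascade(conc))

    def structured_starts(self):
        """Deterministic portfolio: a symmetric profile plus one split
        profile per candidate breaking point k (cell 1 runs the first k
        reactions and excretes X_k; the product flows back).

        At a split optimum the impermeable species carry no exchange flux,
        so their inter-cell gaps vanish; only the handoff intermediate and
        the product show gaps, of size flux / (D n). The split starts
        encode exactly that structure, which also makes them feasible
        (chain fluxes match the split pattern and stay nonnegative)."""
        nC = self.nC
        cbar = np.zeros(nC)
        prev = self.model.substrate_conc
        for r in range(nC):  # every step at half its equilibrium ratio
            cbar[r] = 0.5 * self.kin[r].K_eq * prev
            prev = cbar[r]
        starts = [self.pack_start(np.vstack([cbar, cbar]))]
        D = np.concatenate([self.DX, [self.DP]])
        n2 = max(self.n.min(), 1e-6)
        Jref = max(float(self.J.sum()) + self.J0, 1e-6)
        for k in range(1, self.m + 1):
            gamma = np.zeros(nC)
            gamma[k - 1] = min(0.35, Jref / (2.0 * max(D[k - 1], 1e-9) * n2 * cbar[k - 1]))
            if self.DP > 0:
                gamma[-1] = -min(0.35, Jref / (4.0 * self.DP * n2 * cbar[-1]))
            conc = np.vstack([cbar * (1 + gamma), cbar * (1 - gamma)])
            starts.append(self.pack_start(self._clip_cascade(conc)))
        return starts

    def warm_start_vector(self, sol: "AllocationSolution"):
        conc = np.hstack([sol.state.x_in, sol.state.p_in[:, None]])
        logc = np.log(np.clip(conc, 1.05e-9, 0.95e4)).ravel()
        if self.objective == "max_flux":
            lam = sol.metadata.get("lambda", 1.0)
            return np.concatenate([logc, [max(lam, 0.0)]])
        v = np.maximum(sol.fluxes.V_P, self.J)
        return np.concatenate([logc, v])

    # -- local solve -----------------------------------------------------
    def solve_local(self, z0, options: SolverOptions):
        cons = [{"type": "ineq", "fun": self.ineq}]
        if self.mode != "none":
            cons.append({"type": "eq", "fun": self.eq})
        # starts that violate the flux/driving-force constraints badly send
        # SLSQP into unrecoverable territory; skip them
        viol = float(-self.ineq(z0).min())
        if viol > 10.0 * max(float(self.J.sum()) + self.J0, 1.0):
            return None, False
        maxiter = options.max_iter + 150 * (self.m - 1)
        res = minimize(
            self.objective_fun,
            z0,
            method="SLSQP",
            bounds=self.bounds(),
            constraints=cons,
            options={"maxiter": maxiter, "ftol": options.optimality_tolerance},
        )
        # status 8 ("positive directional derivative for linesearch") is a
        # quasi-convergence stall, status 9 an iteration limit; restarting
        # from the stall point usually either converges or confirms it
        polish = 0
        while not res.success and res.status in (8, 9) and polish < 2:
            res = minimize(
                self.objective_fun, res.x, method="SLSQP", bounds=self.bounds(),
                constraints=cons,
                options={"maxiter": maxiter, "ftol": options.optimality_tolerance},
            )
            polish += 1
        tol = options.constraint_tolerance
        feasible = (
            np.all(np.isfinite(res.x))
            and self.ineq(res.x).min() >= -tol
            and (self.mode == "none" or np.abs(self.eq(res.x)).max() <= 10 * tol)
        )
        # feasible stall points (8/9) enter the candidate pool: the
        # surrogate cost has a kink where a flux crosses zero, precisely at
        # split optima, and SLSQP often reports a stall there after
        # effectively converging; selection by cost keeps the best
        ok = feasible and (bool(res.success) or res.status in (8, 9))
        return res, ok

    # -- solution assembly ----------------------------------------------
    def build_solution(self, z, converged, options: SolverOptions, n_starts_used, extra_meta=None):
        ph = self.physics(z)
        m = self.m
        E_raw = np.maximum(ph["E"], 0.0)
        cost = float(self.n @ E_raw.sum(axis=1))
        thr = ZERO_ENZYME_FRACTION * max(cost, 1e-30)
        E = np.where(E_raw < thr, 0.0, E_raw)
        sums = E.sum(axis=0)
        both_absent = sums == 0
        with np.errstate(invalid="ignore"):
            A = np.where(both_absent, 0.0, (E[0] - E[1]) / np.where(sums == 0, 1.0, sums))

        # D = 0 species keep the population mean as a bookkeeping value;
        # their exchange flux is identically zero either way
        x_out = self.n @ ph["X"]
        state = CompartmentState(ph["X"].copy(), ph["P"].copy(), x_out, max(ph["P_out"], 0.0))
        model_at_opt = self.model.with_enzymes(E_raw)
        fluxes = compute_fluxes(model_at_opt, state)
        J_eff = self.J if self.objective != "max_flux" else ph["lam"] * self.J
        active = ph["v"] - J_eff <= 1e-6 * np.maximum(J_eff, 1.0)
        meta = {"objective": self.objective, "mode": self.mode,
                "restriction": self.restriction}
        if self.objective == "max_flux":
            meta["lambda"] = float(ph["lam"])
            meta["budget"] = float(self.budget)
        if extra_meta:
            meta.update(extra_meta)
        return AllocationSolution(
            enzymes=E, enzymes_raw=E_raw, state=state, cost=cost,
            asymmetries=A, both_absent=both_absent, fluxes=fluxes,
            converged=converged, n_starts_used=n_starts_used,
            seed=options.seed, active_demands=active, metadata=meta,
        )


def _failed_solution(model, options, reason):
    m = model.chain_length
    E = np.zeros((2, m + 2))
    state = CompartmentState(np.full((2, m), 1e-9), np.full(2, 1e-9), np.full(m, 1e-9), 1e-9)
    fluxes = compute_fluxes(model.with_enzymes(E), state)
    return AllocationSolution(
        enzymes=E, enzymes_raw=E, state=state, cost=float("nan"),
        asymmetries=np.zeros(m + 2), both_absent=np.ones(m + 2, bool),
        fluxes=fluxes, converged=False, n_starts_used=0, seed=options.seed,
        active_demands=np.zeros(2, bool), metadata={"infeasible": reason},
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def multistart(model: ConsortiumModel, objective_spec: dict, options: SolverOptions | None = None,
               extra_start_vectors=()) -> AllocationSolution:
    """Best feasible local optimum over a seeded portfolio of starts.

    ``objective_spec`` keys: ``kind`` ("min_cost" or "max_flux"), ``mode``
    ("none", "force_symmetric", "force_split"), ``budget`` (max_flux only).
    Reproducible: the same seed yields the identical selected solution.
    """
    options = options or SolverOptions()
    kind = objective_spec.get("kind", "min_cost")
    mode = objective_spec.get("mode", "none")
    restriction = objective_spec.get(
        "restriction",
        options.symmetry_restriction if mode == "none" and kind == "min_cost" else "none",
    )
    try:
        prob = _ReducedProblem(model, objective=kind, mode=mode,
                               budget=objective_spec.get("budget"), restriction=restriction)
    except InfeasibleModelError as err:
        return _failed_solution(model, options, str(err))

    rng = np.random.default_rng(options.seed)
    starts = list(extra_start_vectors)
    if options.warm_start is not None and options.warm_start.converged:
        starts.append(prob.warm_start_vector(options.warm_start))
    starts += prob.structured_starts()
    starts += [prob.random_start(rng) for _ in range(options.n_starts)]

    candidates = []
    for z0 in starts:
        try:
            res, ok = prob.solve_local(np.asarray(z0, dtype=float), options)
        except (FloatingPointError, ValueError):
            continue
        if ok:
            score = prob.raw_cost(res.x) if kind == "min_cost" else float(res.fun)
            candidates.append((score, res.x))
    n_used = len(starts)
    if not candidates:
        return _failed_solution(model, options, "no start converged to a feasible point")

    candidates.sort(key=lambda t: t[0])
    best_obj, best_z = candidates[0]
    sol = prob.build_solution(best_z, True, options, n_used,
                              {"n_converged": len(candidates)})

    # tie-break at the regime boundary: prefer the symmetric solution when
    # the two branches cost the same within tolerance, and flag it
    if kind == "min_cost" and np.max(np.abs(sol.asymmetries)) > 1e-3:
        rtol = options.boundary_cost_rtol
        for obj, z in candidates[1:]:
            if obj > best_obj * (1 + rtol) + 1e-12:
                break
            alt = prob.build_solution(z, True, options, n_used, {"n_converged": len(candidates)})
            if np.max(np.abs(alt.asymmetries)) <= 1e-3:
                alt.metadata["boundary"] = True
                return alt
    return sol


def minimize_enzyme_cost(model: ConsortiumModel, options: SolverOptions | None = None) -> AllocationSolution:
    """Minimize total enzyme cost C subject to steady state and demands."""
    options = options or SolverOptions()
    return multistart(
        model,
        {"kind": "min_cost", "mode": "none", "restriction": options.symmetry_restriction},
        options,
    )


def minimize_with_symmetry_constraint(model: ConsortiumModel, mode: str,
                                      options: SolverOptions | None = None) -> AllocationSolution:
    """Constrained variants: ``force_symmetric`` imposes identical enzyme
    allocation in both cells; ``force_split`` removes E_S from cell 2."""
    if mode not in ("force_symmetric", "force_split"):
        raise ParameterDomainError("mode must be 'force_symmetric' or 'force_split'")
    options = options or SolverOptions()
    return multistart(model, {"kind": "min_cost", "mode": mode, "restriction": "none"}, options)


def maximize_flux_under_budget(model: ConsortiumModel, enzyme_budget: float,
                               options: SolverOptions | None = None) -> AllocationSolution:
    """Dual formulation: maximize the uniform demand-scaling factor lambda
    such that V_P,i >= lambda J_P,i under a total enzyme budget."""
    if enzyme_budget < 0:
        raise ParameterDomainError("enzyme_budget must be >= 0")
    options = options or SolverOptions()
    if enzyme_budget == 0:
        sol = _failed_solution(model, options, "")
        sol.converged = True
        sol.cost = 0.0
        sol.metadata = {"objective": "max_flux", "lambda": 0.0, "budget": 0.0}
        return sol
    return multistart(
        model,
        {"kind": "max_flux", "mode": "none", "budget": float(enzyme_budget),
         "restriction": options.symmetry_restriction},
        options,
    )


def continuation_sweep(models, options: SolverOptions | None = None,
                       objective_spec: dict | None = None, jump_rtol: float = 0.2):
    """Solve a sequence of models, warm-starting each from the previous
    optimum with a fresh full multistart fallback on large cost jumps.

    Every point also runs a reduced multistart portfolio (structured starts
    plus ``n_starts_sweep`` random starts) so that branch switches across
    the symmetric/asymmetric transition line are not missed. Per-point
    failures are recorded in the returned solutions, not raised.
    """
    options = options or SolverOptions()
    spec = objective_spec or {"kind": "min_cost", "mode": "none",
                              "restriction": options.symmetry_restriction}
    out = []
    prev = options.warm_start
    for idx, model in enumerate(models):
        opts = SolverOptions(
            n_starts=options.n_starts_sweep, seed=int((options.seed + 77003 * idx) % (2**31 - 1)),
            constraint_tolerance=options.constraint_tolerance,
            optimality_tolerance=options.optimality_tolerance,
            symmetry_restriction=options.symmetry_restriction,
            warm_start=prev if (prev is not None and prev.converged) else None,
            max_iter=options.max_iter, n_starts_sweep=options.n_starts_sweep,
            boundary_cost_rtol=options.boundary_cost_rtol,
        )
        sol = multistart(model, spec, opts)
        if (
            prev is not None and prev.converged and sol.converged
            and np.isfinite(prev.cost) and prev.cost > 0
            and abs(sol.cost - prev.cost) / prev.cost > jump_rtol
        ):
            # large jump: retry with the full number of starts before accepting
            opts_full = SolverOptions(
                n_starts=options.n_starts, seed=opts.seed,
                symmetry_restriction=options.symmetry_restriction,
                warm_start=opts.warm_start, max_iter=options.max_iter,
            )
            alt = multistart(model, spec, opts_full)
            if alt.converged and (not sol.converged or alt.cost < sol.cost):
                sol = alt
        out.append(sol)
        if sol.converged:
            prev = sol
    return out
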