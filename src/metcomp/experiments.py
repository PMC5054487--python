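"""Computational experiments on the consortium model.

Phase diagrams of the optimal enzyme asymmetries over the permeability
plane, symmetric-vs-split cost surfaces, demand and population sweeps, the
parameter sensitivity analysis, and the extended multi-intermediate chain
splitting experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterDomainError
from .model import ConsortiumModel
from .optimize import (
    AllocationSolution,
    SolverOptions,
    continuation_sweep,
    minimize_with_symmetry_constraint,
    multistart,
)
from .synthetic import default_consortium, extended_consortium, sample_perturbed_parameters

__all__ = [
    "PhaseDiagramResult",
    "SweepResult",
    "SensitivityResult",
    "phase_diagram",
    "classify_regime",
    "demand_and_population_sweeps",
    "sensitivity_analysis",
    "extended_split_experiment",
    "split_point",
    "find_regime_boundary",
]

REGIMES = ("neutralist", "cheater", "complementation", "boundary")

#: default relative tolerance on asymmetries/fluxes for regime calls
REGIME_TOL = 1e-3

#: default permeability grid: 13 log-spaced points in [1e-2, 30] plus 0
DEFAULT_D_GRID = np.concatenate([[0.0], np.geomspace(1e-2, 30.0, 13)])
#: default inhibition strengths (four phase-diagram slices)
DEFAULT_INV_K_I = (0.1, 1.0, 10.0, 30.0)


@dataclass
class PhaseDiagramResult:
    """One record per (D_X, D_P, 1/K_I) grid point."""

    records: list = field(default_factory=list)
    solutions: list = field(default_factory=list)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_dict(self) -> dict:
        return {"kind": "phase_diagram", "seed": self.seed, "records": self.records}


@dataclass
class SweepResult:
    """Per-point summaries along a single swept parameter."""

    parameter: str = ""
    values: list = field(default_factory=list)
    records: list = field(default_factory=list)
    solutions: list = field(default_factory=list)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_dict(self) -> dict:
        return {"kind": "sweep", "parameter": self.parameter, "seed": self.seed,
                "records": self.records}


@dataclass
class SensitivityResult:
    """Sample covariance (and Pearson correlation) between the optimal
    E_S asymmetry A_S and each perturbed parameter."""

    parameters: list
    covariance: dict
    pearson: dict
    n_samples: int
    n_excluded: int
    rel_magnitude: float
    seed: int
    base_point: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameters,
                "covariance": [self.covariance[p] for p in self.parameters],
                "pearson": [self.pearson[p] for p in self.parameters],
            }
        )

    def to_dict(self) -> dict:
        return {"kind": "sensitivity", "seed": self.seed, "n_samples": self.n_samples,
                "n_excluded": self.n_excluded, "rel_magnitude": self.rel_magnitude,
                "covariance": self.covariance, "pearson": self.pearson,
                "base_point": self.base_point}


def _solution_record(sol: AllocationSolution, **extra) -> dict:
    m = sol.enzymes.shape[1] - 2
    rec = dict(extra)
    rec.update(
        cost=float(sol.cost),
        converged=bool(sol.converged),
        A_S=float(sol.asymmetries[0]),
        A_P=float(sol.asymmetries[-1]),
        residual_norm=float(sol.residual_norm),
    )
    if m == 1:
        rec["A_X"] = float(sol.asymmetries[1])
    else:
        for k in range(1, m + 1):
            rec[f"A_X{k}"] = float(sol.asymmetries[k])
    total = sol.enzymes_raw.sum()
    rec["E_S2_frac"] = float(sol.enzymes_raw[1, 0] / total) if total > 0 else 0.0
    rec["E_X1_frac"] = float(sol.enzymes_raw[0, 1] / total) if total > 0 else 0.0
    rec["complete_split"] = bool(rec["E_S2_frac"] <= 1e-6 and rec["E_X1_frac"] <= 1e-6
                                 and abs(rec["A_S"]) >= 1 - REGIME_TOL)
    if sol.converged:
        try:
            rec["regime"] = classify_regime(sol)
        except ParameterDomainError:
            rec["regime"] = "boundary"
    else:
        rec["regime"] = "failed"
    return rec


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------


def classify_regime(solution: AllocationSolution, tol: float = REGIME_TOL) -> str:
    """Label the optimal-allocation outcome.

    * ``neutralist``: both cells allocate identically, nothing is exchanged.
    * ``cheater``: the pathway head runs in one cell only; the intermediate
      leaks to the other cell and no product flows back.
    * ``complementation``: the intermediate flows one way and the product
      is shuttled back the other.
    * ``boundary``: anything in between.

    Labels are invariant under relabeling of the two cells. Refuses
    unconverged solutions.
    """
    if not solution.converged:
        raise ParameterDomainError("cannot classify an unconverged solution")
    demands = solution.fluxes.V_P
    scale = max(float(np.sum(np.abs(demands))), 1.0)
    ftol = tol * scale
    A = solution.asymmetries
    # producer = cell with the larger E_S share; relabel so it is "cell 1"
    producer = 0 if A[0] >= 0 else 1
    other = 1 - producer
    sign = 1.0 if producer == 0 else -1.0
    U_X = solution.fluxes.U_X[producer]
    U_P = float(solution.fluxes.U_P[producer])
    max_exchange = float(
        np.max(np.abs(np.concatenate([solution.fluxes.U_X.ravel(), solution.fluxes.U_P])))
    )
    if np.max(np.abs(A)) <= tol and max_exchange <= ftol:
        return "neutralist"
    a_s = sign * A[0]
    if a_s >= 1 - tol and np.max(U_X) > ftol:
        if U_P < -ftol:
            return "complementation"
        if abs(U_P) <= ftol:
            return "cheater"
    return "boundary"


# ---------------------------------------------------------------------------
# phase diagrams
# ---------------------------------------------------------------------------


def _snake(values_outer, values_inner):
    """Grid walk that reverses direction on every row (good warm starts)."""
    for i, a in enumerate(values_outer):
        inner = values_inner if i % 2 == 0 else values_inner[::-1]
        for b in inner:
            yield a, b


def phase_diagram(model_template: ConsortiumModel | None = None,
                  D_X_values=None, D_P_values=None, inv_K_I_values=None,
                  options: SolverOptions | None = None) -> PhaseDiagramResult:
    """Optimal asymmetries/cost/regime over a (D_X, D_P) grid for each
    inhibition strength, solved with warm-started continuation along a
    snake path through the grid. Per-point failures are recorded."""
    options = options or SolverOptions()
    D_X_values = DEFAULT_D_GRID if D_X_values is None else np.asarray(D_X_values, dtype=float)
    D_P_values = DEFAULT_D_GRID if D_P_values is None else np.asarray(D_P_values, dtype=float)
    inv_K_I_values = DEFAULT_INV_K_I if inv_K_I_values is None else inv_K_I_values
    if len(D_X_values) == 0 or len(D_P_values) == 0 or len(inv_K_I_values) == 0:
        raise ParameterDomainError("grids must be nonempty")
    base_overrides = {} if model_template is None else None

    result = PhaseDiagramResult(seed=options.seed)
    for inv_K_I in inv_K_I_values:
        points = list(_snake(D_X_values, D_P_values))
        models = []
        for DX, DP in points:
            if base_overrides is not None:
                models.append(default_consortium(inv_K_I=inv_K_I, D_X=DX, D_P=DP))
            else:
                mt = model_template
                kin = [type(k)(**k.to_dict()) for k in mt.kinetics]
                kin[0].inv_K_I = inv_K_I
                D = mt.permeabilities.copy()
                D[:-1] = DX
                D[-1] = DP
                models.append(
                    ConsortiumModel(
                        substrate_conc=mt.substrate_conc, chain_length=mt.chain_length,
                        kinetics=kin, permeabilities=D, host_demand=mt.host_demand,
                        total_cells=mt.total_cells, cells=mt.cells,
                    )
                )
        sols = continuation_sweep(models, options)
        for (DX, DP), sol in zip(points, sols):
            result.records.append(
                _solution_record(sol, D_X=float(DX), D_P=float(DP), inv_K_I=float(inv_K_I))
            )
            result.solutions.append(sol)
    return result


# ---------------------------------------------------------------------------
# demand / population sweeps
# ---------------------------------------------------------------------------


def demand_and_population_sweeps(model_template: ConsortiumModel, sweep: str, values,
                                 options: SolverOptions | None = None) -> SweepResult:
    """Sweep one structural parameter with warm-started continuation.

    ``sweep`` is one of ``"rho_J"`` (demand asymmetry, total demand held at
    J_P,1 + J_P,2 of the template), ``"J_P_0"`` (host demand; requires
    D_P > 0 for positive values) or ``"n1"`` (population fraction).

    For the cell-asymmetric sweeps (``rho_J``, ``n1``) the A_S >= 0
    restriction is lifted: breaking the symmetry between the cells breaks
    the +/- degeneracy of the solutions, and the optimal orientation can be
    reversed (e.g. complete splitting with [E_S,1] = [E_X,2] = 0 at large
    demand asymmetry).
    """
    values = list(np.atleast_1d(values))
    if not values:
        raise ParameterDomainError("sweep values must be nonempty")
    options = options or SolverOptions()
    mt = model_template
    models = []
    for val in values:
        total = float(mt.demands.sum())
        demands, fractions, host = tuple(mt.demands), tuple(mt.fractions), mt.host_demand
        if sweep == "rho_J":
            if not 0 <= val < 1:
                raise ParameterDomainError("rho_J must lie in [0, 1)")
            demands = (total / 2 * (1 + val), total / 2 * (1 - val))
        elif sweep == "J_P_0":
            if val < 0:
                raise ParameterDomainError("J_P_0 must be >= 0")
            host = float(val)
        elif sweep == "n1":
            if not 0 < val < 1:
                raise ParameterDomainError("n1 must lie in (0, 1)")
            fractions = (float(val), 1.0 - float(val))
        else:
            raise ParameterDomainError("sweep must be 'rho_J', 'J_P_0' or 'n1'")
        models.append(
            default_consortium(
                substrate_conc=mt.substrate_conc, chain_length=mt.chain_length,
                kinetics=[type(k)(**k.to_dict()) for k in mt.kinetics],
                permeabilities=mt.permeabilities.copy(), host_demand=host,
                total_cells=mt.total_cells, demands=demands, fractions=fractions,
            )
        )
    spec = None
    if sweep in ("rho_J", "n1"):
        spec = {"kind": "min_cost", "mode": "none", "restriction": "none"}
    sols = continuation_sweep(models, options, objective_spec=spec)
    result = SweepResult(parameter=sweep, values=[float(v) for v in values], seed=options.seed)
    for val, sol in zip(values, sols):
        rec = _solution_record(sol, **{sweep: float(val)})
        total = sol.enzymes_raw.sum()
        # reversed-orientation complete split (cell 1 lacks E_S instead)
        rec["E_S1_frac"] = float(sol.enzymes_raw[0, 0] / total) if total > 0 else 0.0
        rec["E_X2_frac"] = float(sol.enzymes_raw[1, 1] / total) if total > 0 else 0.0
        result.records.append(rec)
        result.solutions.append(sol)
    return result


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------


def find_regime_boundary(inv_K_I: float = 10.0, D_P: float = 1.0,
                         bracket=(0.05, 30.0), options: SolverOptions | None = None,
                         rtol: float = 1e-2) -> float:
    """D_X at which the symmetric and split strategies cost the same
    (bisection on the cost difference at fixed D_P).

    The constrained solves need a full multistart portfolio: near the
    crossing the branch costs differ by ~1e-2 while an under-started solve
    can miss the best branch optimum by ~0.3."""
    options = options or SolverOptions(n_starts=12)

    def gap(DX):
        model = default_consortium(inv_K_I=inv_K_I, D_X=DX, D_P=D_P)
        c_sym = minimize_with_symmetry_constraint(model, "force_symmetric", options).cost
        c_split = minimize_with_symmetry_constraint(model, "force_split", options).cost
        return c_sym - c_split

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if not (g_lo < 0 < g_hi):
        raise ParameterDomainError(
            f"no symmetric/split crossing in D_X bracket {bracket} (gaps {g_lo:.3g}, {g_hi:.3g})"
        )
    while hi / lo > 1 + rtol:
        mid = float(np.sqrt(lo * hi))
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def sensitivity_analysis(model_template: ConsortiumModel | None = None,
                         rel_magnitude: float = 0.3, n_samples: int = 200,
                         seed: int = 0, options: SolverOptions | None = None) -> SensitivityResult:
    """Covariance between the optimal A_S and each randomly perturbed
    parameter, at a base point on the symmetric/split regime boundary.

    Each sample perturbs every positive parameter multiplicatively
    (k * exp(u), u ~ U(-delta, delta)), re-optimizes the allocation, and
    records A_S. Unconverged samples are excluded and counted.
    """
    if n_samples < 2:
        raise ParameterDomainError("n_samples must be >= 2")
    options = options or SolverOptions(n_starts=8)
    if model_template is None:
        DX_star = find_regime_boundary()
        model_template = default_consortium(inv_K_I=10.0, D_X=DX_star, D_P=1.0)
    rng = np.random.default_rng(seed)
    rows, A_vals = [], []
    n_excluded = 0
    for j in range(n_samples):
        sample = sample_perturbed_parameters(model_template, rel_magnitude, rng)
        opts = SolverOptions(n_starts=options.n_starts,
                             seed=int((seed + 50021 * j) % (2**31 - 1)),
                             symmetry_restriction="A_S_nonnegative")
        sol = multistart(sample.model, {"kind": "min_cost", "mode": "none",
                                        "restriction": "A_S_nonnegative"}, opts)
        if not sol.converged:
            n_excluded += 1
            continue
        rows.append(sample.values)
        A_vals.append(float(sol.asymmetries[0]))

    names = list(rows[0]) if rows else []
    A = np.asarray(A_vals)
    cov, pear = {}, {}
    for name in names:
        k = np.asarray([r[name] for r in rows])
        c = float(np.cov(A, k, ddof=1)[0, 1]) if len(A) > 1 else 0.0
        cov[name] = c
        sd = A.std(ddof=1) * k.std(ddof=1)
        pear[name] = float(c / sd) if sd > 0 else 0.0
    return SensitivityResult(
        parameters=names, covariance=cov, pearson=pear,
        n_samples=len(A_vals), n_excluded=n_excluded,
        rel_magnitude=rel_magnitude, seed=seed,
        base_point={"inv_K_I": model_template.kinetics[0].inv_K_I,
                    "D_X": float(model_template.permeabilities[0]),
                    "D_P": model_template.D_P},
    )


# ---------------------------------------------------------------------------
# extended chain
# ---------------------------------------------------------------------------


def split_point(solution: AllocationSolution, tol: float = 0.05):
    """Breaking point of an allocation: the k such that cell 1 expresses
    the first k synthesis enzymes and cell 2 the remaining ones
    (consumption enzymes excluded from the rule). Returns None when no
    clean partition exists (e.g. symmetric allocation).

    An enzyme counts as expressed when it exceeds ``tol`` times its cell's
    total enzyme. The default of 5% reflects that optimal split
    allocations typically keep trace downstream expression in the producer
    cell (the permeable intermediate is mostly, not entirely, shuttled),
    an order of magnitude below the head enzymes' share."""
    if not solution.converged:
        raise ParameterDomainError("cannot evaluate the split point of an unconverged solution")
    E = solution.enzymes
    m_plus_1 = E.shape[1] - 1  # number of synthesis reactions
    active = []
    for i in range(2):
        total = E[i].sum()
        if total <= 0:
            return None
        active.append(E[i, :m_plus_1] > tol * total)
    a1, a2 = active
    for k in range(1, m_plus_1):
        head = np.zeros(m_plus_1, dtype=bool)
        head[:k] = True
        if np.array_equal(a1, head) and np.array_equal(a2, ~head):
            return k
    return None


def extended_split_experiment(permeable_index: int, m: int = 5,
                              options: SolverOptions | None = None,
                              model: ConsortiumModel | None = None):
    """Optimize the extended chain in which only P and one intermediate
    permeate, and report where the pathway splits between the two cells.

    Returns ``(solution, split_index)``.
    """
    options = options or SolverOptions()
    if model is None:
        model = extended_consortium(permeable_index, m=m)
    sol = multistart(model, {"kind": "min_cost", "mode": "none",
                             "restriction": "A_S_nonnegative"}, options)
    idx = split_point(sol) if sol.converged else None
    return sol, idx
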