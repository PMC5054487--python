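"""Two-population consortium model: state containers, balances, dynamics.

The consortium consists of two bacterial populations (fractions n1 + n2 = 1,
total cell count N) that both encode the same linear pathway

    S -> X_1 -> ... -> X_m -> P        (m + 1 reversible synthesis steps)
    P -> biomass                       (irreversible consumption step)

inside a shared host compartment. Intermediates X_k and the end product P
cross the membranes by first-order diffusion; the substrate S is held at a
fixed concentration and carries no balance equation. The host consumes
extracellular P at a population-normalized rate J_P,0.

Enzyme-vector layout (canonical ordering, length m + 2 per cell):
index 0 = E_S (reaction S -> X_1), indices 1..m-1 = intermediate
conversions, index m = final synthesis step to P, index m + 1 = E_P
(consumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .errors import ParameterDomainError, StructuralError
from .kinetics import (
    ReactionKinetics,
    consumption_rate,
    synthesis_rate,
    transport_rate,
)

__all__ = [
    "CellPopulation",
    "ConsortiumModel",
    "CompartmentState",
    "SteadyStateSolution",
    "balance_residuals",
    "compute_fluxes",
    "simulate_dynamics",
]

#: residual max-norm below which a state is accepted as steady
STEADY_STATE_TOL = 1e-8


@dataclass
class CellPopulation:
    """One bacterial population: its enzymes, product demand and fraction."""

    enzyme_conc: np.ndarray  # length m+2, canonical ordering
    demand: float = 1.0  # J_P,i, minimum consumption flux
    fraction: float = 0.5  # n_i

    def __post_init__(self) -> None:
        self.enzyme_conc = np.asarray(self.enzyme_conc, dtype=float)
        if np.any(self.enzyme_conc < 0):
            raise ParameterDomainError("enzyme concentrations must be >= 0")
        if self.demand < 0:
            raise ParameterDomainError("demand flux must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ParameterDomainError("population fraction must lie in [0, 1]")


@dataclass
class ConsortiumModel:
    """Two cell populations sharing one linear pathway of m intermediates.

    ``kinetics`` has m + 2 entries: m + 1 synthesis steps followed by the
    consumption step. ``permeabilities`` has m + 1 entries: D for X_1..X_m
    followed by D_P. Only the first synthesis step may carry inhibition, and
    the inhibitor is always P.
    """

    substrate_conc: float = 10.0
    chain_length: int = 1
    kinetics: list = field(default_factory=list)
    permeabilities: np.ndarray = field(default_factory=lambda: np.ones(2))
    host_demand: float = 0.0  # J_P,0 (population-normalized)
    total_cells: float = 1.0  # N; cancels at steady state
    cells: tuple = ()

    def __post_init__(self) -> None:
        m = self.chain_length
        if m < 1:
            raise StructuralError("chain_length must be >= 1")
        if self.substrate_conc <= 0:
            raise ParameterDomainError("substrate_conc must be > 0")
        if self.host_demand < 0:
            raise ParameterDomainError("host_demand must be >= 0")
        if self.total_cells <= 0:
            raise ParameterDomainError("total_cells must be > 0")
        if not self.kinetics:
            self.kinetics = [ReactionKinetics() for _ in range(m + 1)] + [
                ReactionKinetics(reversible=False)
            ]
        if len(self.kinetics) != m + 2:
            raise StructuralError(
                f"need {m + 2} kinetics entries (m+1 synthesis + consumption), got {len(self.kinetics)}"
            )
        for r, kin in enumerate(self.kinetics[1:], start=1):
            if kin.inhibition_mode != "none" or kin.inv_K_I != 0:
                raise StructuralError(
                    f"only the first synthesis reaction may carry inhibition (reaction {r})"
                )
        self.permeabilities = np.asarray(self.permeabilities, dtype=float)
        if self.permeabilities.shape != (m + 1,):
            raise StructuralError(
                f"permeabilities must have length m+1={m + 1}, got {self.permeabilities.shape}"
            )
        if np.any(self.permeabilities < 0):
            raise ParameterDomainError("permeabilities must be >= 0")
        if not self.cells:
            self.cells = (
                CellPopulation(np.ones(m + 2), 1.0, 0.5),
                CellPopulation(np.ones(m + 2), 1.0, 0.5),
            )
        if len(self.cells) != 2:
            raise StructuralError("exactly two cell populations are required")
        for cell in self.cells:
            if cell.enzyme_conc.shape != (m + 2,):
                raise StructuralError("enzyme vectors must have length m+2")
        if abs(self.cells[0].fraction + self.cells[1].fraction - 1.0) > 1e-12:
            raise ParameterDomainError("population fractions must sum to 1")

    # -- convenience accessors -------------------------------------------
    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.cells[0].fraction, self.cells[1].fraction])

    @property
    def demands(self) -> np.ndarray:
        return np.array([self.cells[0].demand, self.cells[1].demand])

    @property
    def enzymes(self) -> np.ndarray:
        """Enzyme matrix, shape (2, m+2)."""
        return np.vstack([self.cells[0].enzyme_conc, self.cells[1].enzyme_conc])

    @property
    def D_P(self) -> float:
        return float(self.permeabilities[-1])

    @property
    def D_X(self) -> np.ndarray:
        return self.permeabilities[:-1]

    def with_enzymes(self, enzymes: np.ndarray) -> "ConsortiumModel":
        """Copy of the model with both cells' enzyme vectors replaced."""
        enzymes = np.asarray(enzymes, dtype=float)
        cells = tuple(
            CellPopulation(enzymes[i].copy(), self.cells[i].demand, self.cells[i].fraction)
            for i in range(2)
        )
        return ConsortiumModel(
            substrate_conc=self.substrate_conc,
            chain_length=self.chain_length,
            kinetics=list(self.kinetics),
            permeabilities=self.permeabilities.copy(),
            host_demand=self.host_demand,
            total_cells=self.total_cells,
            cells=cells,
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "substrate_conc": float(self.substrate_conc),
            "chain_length": int(self.chain_length),
            "kinetics": [k.to_dict() for k in self.kinetics],
            "permeabilities": [float(d) for d in self.permeabilities],
            "host_demand": float(self.host_demand),
            "total_cells": float(self.total_cells),
            "demands": [float(c.demand) for c in self.cells],
            "fractions": [float(c.fraction) for c in self.cells],
            "enzymes": [[float(e) for e in c.enzyme_conc] for c in self.cells],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConsortiumModel":
        cells = tuple(
            CellPopulation(np.asarray(d["enzymes"][i], dtype=float), d["demands"][i], d["fractions"][i])
            for i in range(2)
        )
        return cls(
            substrate_conc=d["substrate_conc"],
            chain_length=d["chain_length"],
            kinetics=[ReactionKinetics.from_dict(k) for k in d["kinetics"]],
            permeabilities=np.asarray(d["permeabilities"], dtype=float),
            host_demand=d["host_demand"],
            total_cells=d["total_cells"],
            cells=cells,
        )

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load_yaml(cls, path) -> "ConsortiumModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CompartmentState:
    """Concentrations in all compartments.

    ``x_in`` has shape (2, m); ``p_in`` shape (2,); ``x_out`` shape (m,);
    ``p_out`` is scalar. Extracellular entries of species with D = 0 are
    carried for bookkeeping but are not part of the dynamical state vector
    (their exchange flux is identically zero).
    """

    x_in: np.ndarray
    p_in: np.ndarray
    x_out: np.ndarray
    p_out: float

    def __post_init__(self) -> None:
        self.x_in = np.atleast_2d(np.asarray(self.x_in, dtype=float))
        self.p_in = np.asarray(self.p_in, dtype=float)
        self.x_out = np.asarray(self.x_out, dtype=float)
        self.p_out = float(self.p_out)
        allv = np.concatenate([self.x_in.ravel(), self.p_in, self.x_out, [self.p_out]])
        if not np.all(np.isfinite(allv)):
            raise ParameterDomainError("concentrations must be finite")

    @property
    def m(self) -> int:
        return self.x_in.shape[1]

    def copy(self) -> "CompartmentState":
        return CompartmentState(self.x_in.copy(), self.p_in.copy(), self.x_out.copy(), self.p_out)

    # -- packing (for ODE integration) -----------------------------------
    def pack(self, model: ConsortiumModel) -> np.ndarray:
        """Flatten the dynamical state: intracellular species always, the
        extracellular ones only for exchangeable (D > 0) species."""
        mask = model.D_X > 0
        parts = [self.x_in.ravel(), self.p_in, self.x_out[mask]]
        if model.D_P > 0:
            parts.append([self.p_out])
        return np.concatenate(parts)

    @classmethod
    def unpack(cls, model: ConsortiumModel, vec: np.ndarray, template: "CompartmentState" = None):
        m = model.chain_length
        mask = model.D_X > 0
        x_in = vec[: 2 * m].reshape(2, m)
        p_in = vec[2 * m : 2 * m + 2]
        x_out = np.zeros(m) if template is None else template.x_out.copy()
        k = 2 * m + 2
        n_ex = int(mask.sum())
        x_out[mask] = vec[k : k + n_ex]
        k += n_ex
        p_out = float(vec[k]) if model.D_P > 0 else (0.0 if template is None else template.p_out)
        return cls(x_in, p_in, x_out, p_out)


@dataclass
class SteadyStateSolution:
    """Concentrations plus every reaction and transport flux, with the
    residual max-norm of the balance equations."""

    state: CompartmentState
    V_syn: np.ndarray  # shape (2, m+1): synthesis fluxes per cell
    V_P: np.ndarray  # shape (2,): consumption fluxes
    U_X: np.ndarray  # shape (2, m): intermediate exchange fluxes
    U_P: np.ndarray  # shape (2,): product exchange fluxes
    residual_norm: float

    @property
    def is_steady(self) -> bool:
        return self.residual_norm <= STEADY_STATE_TOL


def _all_fluxes(model: ConsortiumModel, state: CompartmentState):
    """Evaluate every rate law at the given state."""
    m = model.chain_length
    E = model.enzymes
    S = model.substrate_conc
    V_syn = np.zeros((2, m + 1))
    for r in range(m + 1):
        sub = np.full(2, S) if r == 0 else state.x_in[:, r - 1]
        prod = state.p_in if r == m else state.x_in[:, r]
        inhib = state.p_in if model.kinetics[r].inhibition_mode != "none" else np.zeros(2)
        V_syn[:, r] = synthesis_rate(model.kinetics[r], E[:, r], sub, prod, inhib)
    V_P = consumption_rate(model.kinetics[m + 1], E[:, m + 1], state.p_in)
    U_X = np.zeros((2, m))
    for k in range(m):
        U_X[:, k] = transport_rate(model.D_X[k], state.x_in[:, k], state.x_out[k])
    U_P = transport_rate(model.D_P, state.p_in, np.full(2, state.p_out)) if model.D_P > 0 else np.zeros(2)
    return V_syn, V_P, U_X, U_P


def balance_residuals(model: ConsortiumModel, state: CompartmentState) -> CompartmentState:
    """Time derivatives of every species, returned in state layout.

    Intracellular:  d[X_k,i]/dt = V_{k-1},i - V_k,i - U_{X_k,i}
                    d[P_i]/dt   = V_m,i - V_P,i - U_P,i
    Extracellular:  d[X_k,0]/dt = N (n1 U_{X_k,1} + n2 U_{X_k,2})
                    d[P_0]/dt   = N (n1 U_P,1 + n2 U_P,2 - J_P,0)

    The substrate S is buffered and carries no balance equation.
    Derivative entries for non-exchangeable (D = 0) extracellular species
    are reported as zero.
    """
    m = model.chain_length
    if state.m != m:
        raise StructuralError(f"state has {state.m} intermediates, model has {m}")
    V_syn, V_P, U_X, U_P = _all_fluxes(model, state)
    n = model.fractions
    N = model.total_cells
    dx_in = V_syn[:, :m] - V_syn[:, 1:] - U_X
    dp_in = V_syn[:, m] - V_P - U_P
    dx_out = np.where(model.D_X > 0, N * (n @ U_X), 0.0)
    dp_out = N * (n @ U_P - model.host_demand) if model.D_P > 0 else 0.0
    return CompartmentState(dx_in, dp_in, dx_out, dp_out)


def compute_fluxes(model: ConsortiumModel, state: CompartmentState) -> SteadyStateSolution:
    """Assemble all fluxes and the balance residual max-norm at a state."""
    V_syn, V_P, U_X, U_P = _all_fluxes(model, state)
    resid = balance_residuals(model, state)
    norm = float(
        np.max(
            np.abs(
                np.concatenate(
                    [resid.x_in.ravel(), resid.p_in, resid.x_out.ravel(), [resid.p_out]]
                )
            )
        )
    )
    return SteadyStateSolution(state, V_syn, V_P, U_X, U_P, norm)


def simulate_dynamics(
    model: ConsortiumModel,
    initial: CompartmentState,
    horizon: float,
    n_report: int = 50,
    rtol: float = 1e-9,
    atol: float = 1e-11,
):
    """Integrate the balance equations forward in time.

    Returns ``(times, states)`` where ``states`` is a list of
    :class:`CompartmentState`. Raises ``RuntimeError`` with the integrator
    diagnostics on failure. Concentrations remain nonnegative up to
    integrator tolerance (negative round-off is clipped in the reported
    states).
    """
    if horizon <= 0:
        raise ParameterDomainError("horizon must be > 0")

    def rhs(_t, y):
        st = CompartmentState.unpack(model, np.maximum(y, 0.0), template=initial)
        d = balance_residuals(model, st)
        return d.pack(model)

    y0 = initial.pack(model)
    t_eval = np.linspace(0.0, horizon, n_report)
    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1] if sol.t.size else 0}: {sol.message}")
    states = [
        CompartmentState.unpack(model, np.maximum(sol.y[:, j], 0.0), template=initial)
        for j in range(sol.y.shape[1])
    ]
    return sol.t, states
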