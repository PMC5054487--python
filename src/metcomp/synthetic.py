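"""Generators for every input the analyses need: canonical model
parameterizations, perturbed parameter samples for the sensitivity
analysis, and pathway fixtures for the permeability module.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterDomainError
from .kinetics import ReactionKinetics
from .model import CellPopulation, ConsortiumModel
from .permeability import (
    MetaboliteRecord,
    classify_permeability,
    default_ruleset,
    packaged_trp_pathway_path,
    read_pathway_tsv,
)

__all__ = [
    "default_consortium",
    "extended_consortium",
    "sample_perturbed_parameters",
    "ParameterSample",
    "trp_pathway_fixture",
    "synthetic_pathway",
]

_OVERRIDE_KEYS = {
    "substrate_conc", "chain_length", "inv_K_I", "inhibition_mode", "K_eq",
    "D_X", "D_P", "permeabilities", "demands", "host_demand", "fractions",
    "total_cells", "kinetics",
}


def default_consortium(**overrides) -> ConsortiumModel:
    """The canonical consortium parameterization.

    Every kinetic constant is one (so K_I = 1, i.e. inv_K_I = 1, with
    uncompetitive inhibition on the first step), the chain has a single
    intermediate (m = 1), [S] = 10, population fractions are (1/2, 1/2),
    both cell demands are J_P,i = 1 and the host demand J_P,0 is 0.
    Permeabilities default to D_X = D_P = 1.

    Overrides (applied last): ``substrate_conc``, ``chain_length``,
    ``inv_K_I``, ``inhibition_mode``, ``K_eq`` (applied to every reversible
    step), ``D_X`` (scalar or per-intermediate array), ``D_P``,
    ``permeabilities`` (full vector), ``demands``, ``host_demand``,
    ``fractions``, ``total_cells``, ``kinetics`` (full list). Unknown keys
    raise.
    """
    unknown = set(overrides) - _OVERRIDE_KEYS
    if unknown:
        raise ParameterDomainError(f"unknown override keys: {sorted(unknown)}")

    m = int(overrides.get("chain_length", 1))
    substrate = float(overrides.get("substrate_conc", 10.0))
    inv_K_I = float(overrides.get("inv_K_I", 1.0))
    mode = overrides.get("inhibition_mode", "uncompetitive" if inv_K_I > 0 else "none")
    K_eq = float(overrides.get("K_eq", 1.0))

    if "kinetics" in overrides:
        kinetics = overrides["kinetics"]
    else:
        kinetics = [
            ReactionKinetics(K_eq=K_eq, inv_K_I=inv_K_I if r == 0 else 0.0,
                             inhibition_mode=mode if r == 0 else "none")
            for r in range(m + 1)
        ] + [ReactionKinetics(reversible=False)]

    if "permeabilities" in overrides:
        D = np.asarray(overrides["permeabilities"], dtype=float)
    else:
        D_X = overrides.get("D_X", 1.0)
        D_X = np.full(m, float(D_X)) if np.ndim(D_X) == 0 else np.asarray(D_X, dtype=float)
        D = np.concatenate([D_X, [float(overrides.get("D_P", 1.0))]])

    demands = overrides.get("demands", (1.0, 1.0))
    fractions = overrides.get("fractions", (0.5, 0.5))
    cells = tuple(
        CellPopulation(np.ones(m + 2), float(demands[i]), float(fractions[i])) for i in range(2)
    )
    return ConsortiumModel(
        substrate_conc=substrate,
        chain_length=m,
        kinetics=kinetics,
        permeabilities=D,
        host_demand=float(overrides.get("host_demand", 0.0)),
        total_cells=float(overrides.get("total_cells", 1.0)),
        cells=cells,
    )


def extended_consortium(permeable_index: int, m: int = 5, D_perm: float = 15.0,
                        D_imperm: float = 1e-3, **overrides) -> ConsortiumModel:
    """The extended-chain scenario: m intermediates, K_eq = 4/3 on every
    reversible step, strong inhibition (inv_K_I = 10), [S] = 20, and only
    the product P plus the intermediate ``permeable_index`` (1-based)
    permeable (D = 15; all other intermediates D = 1e-3)."""
    if not 1 <= permeable_index <= m:
        raise ParameterDomainError(f"permeable_index must be in 1..{m}")
    D = np.full(m + 1, D_imperm)
    D[permeable_index - 1] = D_perm
    D[m] = D_perm
    defaults = dict(chain_length=m, substrate_conc=20.0, K_eq=4.0 / 3.0,
                    inv_K_I=10.0, permeabilities=D)
    defaults.update(overrides)
    return default_consortium(**defaults)


# ---------------------------------------------------------------------------
# perturbed parameter samples (sensitivity analysis)
# ---------------------------------------------------------------------------


@dataclass
class ParameterSample:
    """One multiplicatively perturbed parameter set.

    ``values`` maps parameter names to their sampled values;
    ``base_values`` holds the unperturbed ones. Every parameter k is drawn
    as k * exp(u), u ~ Uniform(-delta, +delta), independently.
    """

    model: ConsortiumModel
    values: dict
    base_values: dict
    rel_magnitude: float
    provenance: dict = field(default_factory=dict)


def _parameter_vector(model: ConsortiumModel) -> dict:
    """Positive kinetic/permeability parameters in a fixed order."""
    params = {}
    for r, kin in enumerate(model.kinetics):
        tag = f"r{r}" if r <= model.chain_length else "cons"
        params[f"k_cat_{tag}"] = kin.k_cat
        params[f"K_M_fwd_{tag}"] = kin.K_M_fwd
        if kin.reversible:
            params[f"K_M_rev_{tag}"] = kin.K_M_rev
            params[f"K_eq_{tag}"] = kin.K_eq
        if kin.inv_K_I > 0:
            params["inv_K_I"] = kin.inv_K_I
    params["S"] = model.substrate_conc
    for k in range(model.chain_length):
        if model.permeabilities[k] > 0:
            params[f"D_X{k + 1}"] = float(model.permeabilities[k])
    if model.D_P > 0:
        params["D_P"] = model.D_P
    return params


def sample_perturbed_parameters(base: ConsortiumModel, rel_magnitude: float,
                                rng) -> ParameterSample:
    """Multiplicative log-uniform perturbation of every positive kinetic,
    substrate and permeability parameter (demands and fractions fixed)."""
    if rel_magnitude < 0:
        raise ParameterDomainError("rel_magnitude must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    base_values = _parameter_vector(base)
    factors = {name: float(np.exp(rng.uniform(-rel_magnitude, rel_magnitude)))
               for name in base_values}
    values = {name: base_values[name] * factors[name] for name in base_values}

    m = base.chain_length
    kinetics = []
    for r, kin in enumerate(base.kinetics):
        tag = f"r{r}" if r <= m else "cons"
        kinetics.append(
            ReactionKinetics(
                k_cat=values[f"k_cat_{tag}"],
                K_M_fwd=values[f"K_M_fwd_{tag}"],
                K_M_rev=values.get(f"K_M_rev_{tag}", kin.K_M_rev),
                K_eq=values.get(f"K_eq_{tag}", kin.K_eq),
                inv_K_I=values["inv_K_I"] if kin.inv_K_I > 0 else 0.0,
                inhibition_mode=kin.inhibition_mode,
                reversible=kin.reversible,
            )
        )
    D = base.permeabilities.copy()
    for k in range(m):
        if D[k] > 0:
            D[k] = values[f"D_X{k + 1}"]
    if base.D_P > 0:
        D[m] = values["D_P"]
    model = ConsortiumModel(
        substrate_conc=values["S"],
        chain_length=m,
        kinetics=kinetics,
        permeabilities=D,
        host_demand=base.host_demand,
        total_cells=base.total_cells,
        cells=tuple(
            CellPopulation(c.enzyme_conc.copy(), c.demand, c.fraction) for c in base.cells
        ),
    )
    return ParameterSample(model=model, values=values, base_values=base_values,
                           rel_magnitude=rel_magnitude,
                           provenance={"scheme": "multiplicative log-uniform"})


# ---------------------------------------------------------------------------
# pathway fixtures
# ---------------------------------------------------------------------------


def trp_pathway_fixture():
    """The seven tryptophan-pathway metabolites (chorismate through
    L-tryptophan) with pinned SMILES and indole flagged as channeled.
    Descriptors and class labels are computed on load."""
    records = read_pathway_tsv(packaged_trp_pathway_path())
    ruleset = default_ruleset()
    for rec in records:
        classify_permeability(rec, ruleset)
    return records


def synthetic_pathway(rng, length: int, permeable_positions) -> list:
    """Generate a synthetic pathway whose descriptors make exactly the
    requested interior positions the most permeable (ground truth for
    breaking-point prediction; descriptor values are fabricated, records
    carry no structures).

    The designated positions receive low TPSA (H class); all other
    compounds receive high TPSA (ML/L). With several designated positions
    the ground-truth winner is the one with the lowest TPSA (the documented
    tie-break). The ground truth is recorded in each winning record's
    ``note``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if length < 3:
        raise ParameterDomainError("length must be >= 3")
    permeable_positions = sorted(set(int(p) for p in np.atleast_1d(permeable_positions)))
    if not permeable_positions:
        raise ParameterDomainError("at least one permeable position is required")
    for p in permeable_positions:
        if p <= 1 or p >= length:
            raise ParameterDomainError(
                f"permeable position {p} must be interior (2..{length - 1})"
            )
    records = []
    ruleset = default_ruleset()
    for pos in range(1, length + 1):
        if pos in permeable_positions:
            tpsa = float(rng.uniform(10.0, 55.0))
            logp, mw, hbd, hba = float(rng.uniform(1.0, 3.0)), float(rng.uniform(80, 160)), 1, 1
        else:
            tpsa = float(rng.uniform(150.0, 260.0))
            logp, mw, hbd, hba = float(rng.uniform(-4.0, -1.0)), float(rng.uniform(250, 450)), 4, 8
        rec = MetaboliteRecord(
            name=f"M{pos}", smiles="", position=pos, channeled=False,
            mw=mw, hbd=hbd, hba=hba, logp_primary=logp, tpsa=tpsa,
            note="synthetic descriptor draw",
        )
        classify_permeability(rec, ruleset)
        records.append(rec)
    winner = min(
        (r for r in records if r.position in permeable_positions),
        key=lambda r: (r.tpsa, r.mw),
    )
    winner.note = f"synthetic ground-truth breaking point (position {winner.position})"
    return records
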