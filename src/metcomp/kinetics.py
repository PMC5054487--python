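"""Rate laws for the consortium pathway model.

Three elementary fluxes make up the model: reversible Michaelis-Menten
synthesis steps (the first of which may be feedback-inhibited by the pathway
end product), irreversible Michaelis-Menten consumption of the end product,
and first-order diffusive exchange across the cell membrane.

All quantities are in dimensionless model units; the canonical
parameterization sets every kinetic constant to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ParameterDomainError

__all__ = [
    "ReactionKinetics",
    "synthesis_rate",
    "transport_rate",
    "consumption_rate",
]

INHIBITION_MODES = ("none", "uncompetitive", "competitive")


@dataclass
class ReactionKinetics:
    """Kinetic constants of one enzymatic step.

    Parameters
    ----------
    k_cat : float
        Turnover number (1/time).
    K_M_fwd, K_M_rev : float
        Forward and backward Michaelis constants (concentration). For an
        irreversible (consumption) step only ``K_M_fwd`` is used.
    K_eq : float
        Equilibrium constant (dimensionless).
    inv_K_I : float
        Inverse inhibition constant 1/K_I (1/concentration). Zero means no
        inhibition; the uninhibited reversible Michaelis-Menten law is
        recovered in the limit ``inv_K_I -> 0``.
    inhibition_mode : {"none", "uncompetitive", "competitive"}
        How the end product inhibits the step. ``"uncompetitive"`` scales the
        whole rate by 1/(1 + [P]/K_I); ``"competitive"`` adds [P]/K_I to the
        saturation denominator instead.
    reversible : bool
        Reversible synthesis step vs. irreversible consumption step.
    """

    k_cat: float = 1.0
    K_M_fwd: float = 1.0
    K_M_rev: float = 1.0
    K_eq: float = 1.0
    inv_K_I: float = 0.0
    inhibition_mode: str = "none"
    reversible: bool = True

    def __post_init__(self) -> None:
        for name in ("k_cat", "K_M_fwd", "K_M_rev", "K_eq"):
            if not getattr(self, name) > 0:
                raise ParameterDomainError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.inv_K_I < 0:
            raise ParameterDomainError(f"inv_K_I must be >= 0, got {self.inv_K_I!r}")
        if self.inhibition_mode not in INHIBITION_MODES:
            raise ParameterDomainError(
                f"inhibition_mode must be one of {INHIBITION_MODES}, got {self.inhibition_mode!r}"
            )
        # mode "none" and inv_K_I = 0 are two spellings of the same thing
        if self.inhibition_mode == "none":
            self.inv_K_I = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionKinetics":
        return cls(**d)


def _check_nonnegative(**values) -> None:
    for name, value in values.items():
        arr = np.asarray(value, dtype=float)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ParameterDomainError(f"{name} must be finite and >= 0, got {value!r}")


def synthesis_rate(kin, enzyme, substrate, product_of_step, inhibitor=0.0):
    """Flux of a reversible synthesis step ``A -> B``, possibly inhibited.

    Uncompetitive mode:

        V = k_cat E / (1 + [P]/K_I) * (([A] - [B]/K_eq)/K_M+) /
            (1 + [A]/K_M+ + [B]/K_M-)

    Competitive mode moves the inhibitor term into the saturation
    denominator:

        V = k_cat E * (([A] - [B]/K_eq)/K_M+) /
            (1 + [P]/K_I + [A]/K_M+ + [B]/K_M-)

    The sign of the result equals the sign of the thermodynamic driving
    force ``[A] - [B]/K_eq``; it vanishes at equilibrium. Inputs may be
    scalars or broadcastable arrays.
    """
    _check_nonnegative(
        enzyme=enzyme, substrate=substrate, product_of_step=product_of_step, inhibitor=inhibitor
    )
    enzyme = np.asarray(enzyme, dtype=float)
    a = np.asarray(substrate, dtype=float)
    b = np.asarray(product_of_step, dtype=float)
    p = np.asarray(inhibitor, dtype=float)

    drive = (a - b / kin.K_eq) / kin.K_M_fwd
    denom = 1.0 + a / kin.K_M_fwd + b / kin.K_M_rev
    prefactor = kin.k_cat * enzyme
    if kin.inhibition_mode == "uncompetitive":
        prefactor = prefactor / (1.0 + p * kin.inv_K_I)
    elif kin.inhibition_mode == "competitive":
        denom = denom + p * kin.inv_K_I
    out = prefactor * drive / denom
    return out if out.shape else float(out)


def transport_rate(D, conc_in, conc_out):
    """Diffusive exchange flux ``U = D ([c]_in - [c]_out)``.

    Positive flux means excretion (out of the cell).
    """
    if np.any(np.asarray(D) < 0):
        raise ParameterDomainError(f"permeability D must be >= 0, got {D!r}")
    _check_nonnegative(conc_in=conc_in, conc_out=conc_out)
    out = np.asarray(D, dtype=float) * (np.asarray(conc_in, dtype=float) - np.asarray(conc_out, dtype=float))
    return out if out.shape else float(out)


def consumption_rate(kin, enzyme, product):
    """Irreversible Michaelis-Menten consumption of the end product:
    ``V_P = k_cat E [P] / ([P] + K_M)``. Always >= 0, saturating at k_cat E."""
    _check_nonnegative(enzyme=enzyme, product=product)
    enzyme = np.asarray(enzyme, dtype=float)
    p = np.asarray(product, dtype=float)
    out = kin.k_cat * enzyme * p / (p + kin.K_M_fwd)
    return out if out.shape else float(out)


def unit_synthesis_rate(kin, substrate, product_of_step, inhibitor=0.0):
    """Synthesis rate per unit enzyme (the catalytic efficacy).

    Unlike :func:`synthesis_rate` this skips the nonnegativity checks so it
    can be evaluated freely inside optimizers; it is the same expression with
    E = 1.
    """
    a = np.asarray(substrate, dtype=float)
    b = np.asarray(product_of_step, dtype=float)
    p = np.asarray(inhibitor, dtype=float)
    drive = (a - b / kin.K_eq) / kin.K_M_fwd
    denom = 1.0 + a / kin.K_M_fwd + b / kin.K_M_rev
    pref = kin.k_cat
    if kin.inhibition_mode == "uncompetitive":
        pref = pref / (1.0 + p * kin.inv_K_I)
    elif kin.inhibition_mode == "competitive":
        denom = denom + p * kin.inv_K_I
    return pref * drive / denom


def unit_consumption_rate(kin, product):
    """Consumption rate per unit enzyme."""
    p = np.asarray(product, dtype=float)
    return kin.k_cat * p / (p + kin.K_M_fwd)
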