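"""Exception types shared across the package."""


class ParameterDomainError(ValueError):
    """A kinetic constant, concentration or permeability is outside its domain."""


class StructuralError(ValueError):
    """Model components have inconsistent shapes (chain length vs. vectors)."""


class InfeasibleModelError(ValueError):
    """The optimization problem is infeasible as posed (e.g. host demand
    with an impermeable product)."""
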