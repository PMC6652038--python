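"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A spec, parameter set or scenario is malformed."""


class ConsistencyError(RuntimeError):
    """An internal invariant that should hold under the model hypotheses failed.

    Raised, e.g., when the equilibrium condition has several sign changes
    (uniqueness violated, typically by a custom incidence function that breaks
    the monotonicity hypotheses) or when a characteristic-equation residual
    exceeds its tolerance.
    """


class DegenerateThresholdError(RuntimeError):
    """The basic reproduction number sits on the threshold R0 = 1.

    The existence theory for the positive equilibrium only covers R0 < 1 and
    R0 > 1; parameter sets within the threshold band are flagged instead of
    solved.
    """


class IntegrationError(RuntimeError):
    """Base class for failures of the DDE integrator."""


class DivergenceError(IntegrationError):
    """A state component exceeded 1000x its theoretical ultimate bound."""


class NegativityError(IntegrationError):
    """A state component went negative beyond the round-off clipping band."""
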