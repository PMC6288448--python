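"""Exception hierarchy shared across the package."""


class HGTSimError(Exception):
    """Base class for all hgtsim errors."""


class InvalidInputError(HGTSimError, ValueError):
    """An argument violates a precondition (negative concentration, R1 > R0, ...)."""


class InfeasibleExperimentError(HGTSimError, ValueError):
    """An end-point experiment is inconsistent with the one-hit mass-action model.

    Raised when the argument of a logarithm in the end-point formula is
    non-positive, i.e. the data imply more conversions than available vector.
    """


class ConfigurationError(HGTSimError, ValueError):
    """A simulation or generator configuration is invalid or incomplete."""
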