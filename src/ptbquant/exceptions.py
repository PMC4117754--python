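"""Exception hierarchy shared across the analysis stages."""


class PtbQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PtbQuantError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class DomainError(PtbQuantError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(PtbQuantError, ValueError):
    """Too few observations to perform the requested fit."""


class NonBinomialShapeError(PtbQuantError, ValueError):
    """Linearized step-count data do not have the decreasing slope a
    binomial occupancy model requires."""


class NoBindingError(PtbQuantError, ValueError):
    """A titration shows no positive dependence of bound/free on protein
    concentration, so no dissociation constant can be extracted."""


class SchemaError(PtbQuantError, ValueError):
    """An input table does not have the expected columns or types."""
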