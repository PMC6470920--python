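"""Exception hierarchy."""


class ChiroscanError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ChiroscanError, ValueError):
    """An argument lies outside the mathematical domain of an operation
    (e.g. non-positive distance, dielectric constant below 1)."""


class ParameterizationError(ChiroscanError, KeyError):
    """A typed atom, bond, angle, dihedral or pair does not resolve to a
    force-field parameter entry."""


class SingularityError(ChiroscanError):
    """Two atoms coincide numerically, making a pair energy undefined."""


class ParseError(ChiroscanError, ValueError):
    """A structure or parameter file could not be parsed."""
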