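"""Exception hierarchy."""


class WnetgenError(Exception):
    """Base class for all package errors."""


class InvalidNetworkError(WnetgenError):
    """A matrix violates the weighted-network invariants."""


class DisconnectedNetworkError(WnetgenError):
    """The nonzero pattern is not connected; the Perron eigenvector is not
    unique / not strictly positive."""


class UndefinedSkewnessError(WnetgenError):
    """Skewness requested for a homogeneous eigenvector (variance zero)."""


class CriteriaError(WnetgenError):
    """Generation criteria are invalid or infeasible."""


class ParseError(WnetgenError):
    """A network file could not be parsed."""
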