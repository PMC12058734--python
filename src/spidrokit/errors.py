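"""Exception hierarchy shared across the toolkit."""


class SpidrokitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(SpidrokitError):
    """Malformed input file; message names the offending line."""


class ValidationError(SpidrokitError):
    """Input violates an operation precondition."""


class ConfigurationError(SpidrokitError):
    """A lookup table or parameter set is incomplete or inconsistent."""


class TopologyError(SpidrokitError):
    """A DNA cassette lacks the site layout an operation requires."""


class LigationError(SpidrokitError):
    """Cohesive ends offered for ligation are incompatible."""


class PlanError(SpidrokitError):
    """A synthetic-data plan is internally inconsistent."""
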