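"""Exception hierarchy shared across the package."""


class DfconnError(Exception):
    """Base class for all package errors."""


class ParseError(DfconnError):
    """Malformed input file; message names the offending line."""


class ValidationError(DfconnError, ValueError):
    """Inputs violate a documented precondition or invariant."""


class RangeError(DfconnError, ValueError):
    """A residue position falls outside the declared span."""


class EmptySelectionError(DfconnError, ValueError):
    """A frame/atom selection retained nothing."""


class InsufficientDataError(DfconnError, ValueError):
    """Fewer frames than the statistic requires."""


class UnderdeterminedError(DfconnError, ValueError):
    """Too few atoms to determine a rigid superposition."""


class ConfigurationError(DfconnError, RuntimeError):
    """The input lacks information the requested analysis needs."""
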