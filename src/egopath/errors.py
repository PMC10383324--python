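"""Exception hierarchy.

Every user-facing failure mode maps onto one of these; internal contract
violations raise :class:`ContractError` so callers can distinguish bad input
from a bug in the calling code.
"""


class EgopathError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EgopathError, ValueError):
    """A scenario or run configuration is internally inconsistent."""


class FormatError(EgopathError, ValueError):
    """An input file violates its declared dialect; message names the location."""


class UsageError(EgopathError, ValueError):
    """An operation was called with arguments outside its contract."""


class ContractError(EgopathError, RuntimeError):
    """Caller violated a documented precondition (e.g. unrestricted background)."""


class PipelineError(EgopathError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
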