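"""Exception hierarchy used throughout the package."""


class MacrogrnError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MacrogrnError, ValueError):
    """A file could not be parsed; the message names the file and line."""


class ValidationError(MacrogrnError, ValueError):
    """An in-memory object violates one of its invariants."""


class UsageError(MacrogrnError, ValueError):
    """An operation was called with arguments outside its contract."""


class DependencyError(MacrogrnError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
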