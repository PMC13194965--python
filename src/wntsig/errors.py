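"""Exception hierarchy.

Every error raised by the package derives from :class:`WntsigError` so
callers (and the CLI) can map failure classes to distinct exit codes.
"""


class WntsigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WntsigError):
    """An invalid configuration value; the message names the offending field."""


class UsageError(WntsigError):
    """An operation was called with arguments outside its contract."""


class SchemaError(WntsigError):
    """An input file or table violates the expected schema."""


class DegenerateDataError(WntsigError):
    """Data that makes the requested statistic undefined (e.g. zero variance)."""


class ScoringError(WntsigError):
    """A signature could not be scored against a cohort."""


class ClassificationError(WntsigError):
    """A gene could not be assigned a regulation direction."""
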