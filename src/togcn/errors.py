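"""Typed errors raised across the package.

Every reader/validator raises one of these with a message naming the
offending record (gene id, sample id, line number) so failures are
actionable from the command line.
"""


class TogcnError(Exception):
    """Base class for all package errors."""


class ParseError(TogcnError):
    """A file could not be parsed (malformed line, wrong field count)."""


class ValidationError(TogcnError):
    """Parsed data violates a domain invariant (negative value, duplicate id)."""


class ConfigError(TogcnError):
    """A configuration value is missing, inconsistent, or infeasible."""


class PipelineError(TogcnError):
    """A pipeline stage failed; message names the stage and the cause."""
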