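"""Exception hierarchy for the toolkit.

All user-facing failures derive from :class:`MetassemblyError` so callers
(and the CLI) can catch one base class.
"""


class MetassemblyError(Exception):
    """Base class for all toolkit errors."""


class InputError(MetassemblyError):
    """A referenced input (file, path) is missing or unreadable."""


class FormatError(MetassemblyError):
    """An input file exists but does not conform to its expected format."""


class ValidationError(MetassemblyError):
    """Inputs parse but violate a semantic invariant (duplicate ids,
    illegal alphabet, inconsistent parameters, ...)."""
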