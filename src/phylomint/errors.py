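"""Exception hierarchy for phylomint.

Every error raised by the library derives from :class:`PhyloMIntError`, so
callers (and the CLI) can catch one type. Subclasses mark the contract that
was violated rather than the module that raised it.
"""


class PhyloMIntError(Exception):
    """Base class for all phylomint errors."""


class InputFormatError(PhyloMIntError):
    """A file could not be parsed in the expected format."""


class EmptyModelError(PhyloMIntError):
    """A metabolic model contained no usable reactions."""


class UndefinedIndexError(PhyloMIntError):
    """An interaction index is undefined (e.g. empty seed set of A)."""


class ValidationError(PhyloMIntError):
    """An argument violated a precondition."""


class ConfigurationError(PhyloMIntError):
    """Inconsistent run configuration (duplicate ids, missing labels...)."""
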