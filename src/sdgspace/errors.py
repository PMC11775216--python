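"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`SDGSpaceError`, so callers (and the
CLI) can distinguish bad inputs from genuine bugs with one ``except`` clause.
"""


class SDGSpaceError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(SDGSpaceError):
    """An input table is missing columns or uses an unknown vocabulary."""


class IntegrityError(SDGSpaceError):
    """An input table violates a content invariant (bounds, duplicates)."""


class DegenerateInputError(SDGSpaceError):
    """An operation received input on which its result is undefined."""


class DegeneracyError(DegenerateInputError):
    """The spectral/reflections indices are undefined for this matrix."""
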