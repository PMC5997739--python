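"""Exception hierarchy.

All scalecraft-specific errors derive from :class:`ScalecraftError` so
callers can catch the whole family; each also derives from the closest
built-in (``ValueError``, ``KeyError``, ...) so generic handling works.
"""


class ScalecraftError(Exception):
    """Base class for all scalecraft errors."""


class ItemLookupError(ScalecraftError, KeyError):
    """An item label is not present in the structure or subset."""


class SubsetSizeError(ScalecraftError, ValueError):
    """A subset is too small (or too large) for the requested statistic."""


class DegenerateInputError(ScalecraftError, ValueError):
    """The input has no variance where variance is required."""


class MissingCriterionError(ScalecraftError, ValueError):
    """Item-criterion correlations are required but absent."""


class EnumerationCapError(ScalecraftError, RuntimeError):
    """An exhaustive search would exceed the configured subset cap."""


class ParseError(ScalecraftError, ValueError):
    """A file does not conform to the expected CSV schema."""
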