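"""Exception hierarchy for readrescue.

All pipeline stages raise subclasses of :class:`ReadRescueError` so callers can
distinguish configuration mistakes from data corruption.
"""


class ReadRescueError(Exception):
    """Base class for all readrescue errors."""


class InvalidParameterError(ReadRescueError, ValueError):
    """A parameter violates its documented precondition."""


class PlacementError(ReadRescueError):
    """Binding-site planting could not satisfy the packing constraints."""


class ParseError(ReadRescueError, ValueError):
    """A record in an input file is malformed; message carries the position."""


class MalformedTaxonomyError(ReadRescueError, ValueError):
    """Taxonomy edge list contains a cycle, orphan, or duplicate root."""


class DataIntegrityError(ReadRescueError):
    """Cross-referenced records disagree (e.g. alignment beyond chromosome)."""


class ConfigurationError(ReadRescueError, ValueError):
    """A stage was invoked with an unusable configuration (e.g. empty database)."""


class DegenerateInputError(ReadRescueError, ValueError):
    """Statistical input admits no test (e.g. both samples have zero variance)."""
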