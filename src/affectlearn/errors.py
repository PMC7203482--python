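"""Exception hierarchy for the affectlearn package."""


class AffectLearnError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AffectLearnError, ValueError):
    """An on-disk file violates the expected stream/metadata format."""


class IncompleteSessionError(AffectLearnError, ValueError):
    """A session directory is missing one or more required streams."""


class InsufficientDataError(AffectLearnError, ValueError):
    """Not enough samples/rows to carry out the requested computation."""


class InvalidArgumentError(AffectLearnError, ValueError):
    """An argument violates a documented precondition."""
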