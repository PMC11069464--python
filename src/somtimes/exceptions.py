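"""Exception hierarchy shared across the package."""


class SomtimesError(Exception):
    """Base class for all package-specific errors."""


class LengthMismatchError(SomtimesError, ValueError):
    """Two series (or label vectors) that must share a length do not."""


class ParameterError(SomtimesError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyInputError(SomtimesError, ValueError):
    """An operation received an empty dataset or candidate list."""


class FormatError(SomtimesError, ValueError):
    """A file does not conform to the expected dialect (e.g. ragged rows)."""


class DegenerateInputError(SomtimesError, ValueError):
    """Input is too small for the statistic to be defined."""


class TooShortError(SomtimesError, ValueError):
    """A conversation is too short to stratify into deciles."""
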