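"""Exception hierarchy used across the pipeline."""


class TractUQError(Exception):
    """Base class for all package errors."""


class FormatError(TractUQError):
    """A file's structure is inconsistent (e.g. bval count vs image frames)."""


class DataError(TractUQError):
    """Input values are unusable (non-finite, empty mask, all-zero b0)."""


class SelectionError(TractUQError):
    """A shell/frame selection matched nothing usable."""


class ConditioningError(TractUQError):
    """A linear system is rank-deficient or too ill-conditioned to solve."""


class ShapeError(TractUQError):
    """Array shapes are mutually inconsistent."""


class ConfigurationError(TractUQError):
    """A configuration value is invalid for the requested operation."""
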