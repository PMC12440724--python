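"""Exception types shared across the package."""


class PerifuseError(Exception):
    """Base class for package errors."""


class ParameterError(PerifuseError, ValueError):
    """An argument violates a documented precondition."""


class EmptyROIError(PerifuseError, ValueError):
    """A mask that must contain at least one pixel is empty."""


class StrategyError(PerifuseError, ValueError):
    """An invalid color/ROI/fusion combination was requested."""


class ShapeMismatchError(PerifuseError, ValueError):
    """Two arrays that must be in pixel register have different shapes."""
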