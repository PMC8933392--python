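"""Exception hierarchy shared across the pipeline stages."""


class HistogateError(Exception):
    """Base class for all histogate errors."""


class ValidationError(HistogateError, ValueError):
    """A parameter or input violates a documented precondition."""


class PlacementError(HistogateError, RuntimeError):
    """Synthetic nuclei could not be placed without overlap."""


class UndefinedScoreError(HistogateError, ZeroDivisionError):
    """Percent positive is undefined (no hematoxylin-positive cells)."""


class ZeroVarianceError(HistogateError, ValueError):
    """A correlation or mixture fit was requested on constant data."""
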