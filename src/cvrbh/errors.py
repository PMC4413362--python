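"""Exception and warning types raised across the package."""


class CvrBhError(Exception):
    """Base class for all package errors."""


class NoBreathsError(CvrBhError):
    """Capnograph trace contains no detectable breaths (flat / degenerate)."""


class CoverageError(CvrBhError):
    """Recorded trace does not span the breath-hold paradigm."""


class UnboundedHoldError(CvrBhError):
    """A breath-hold window lacks a bounding end-tidal breath before or after."""


class ResolutionError(CvrBhError):
    """Sampling step of a series does not match the expected resolution."""


class DegenerateRegressorError(CvrBhError):
    """GLM regressor is constant (zero variance), so no slope is estimable."""


class SearchFailureError(CvrBhError):
    """Every candidate delay produced a degenerate fit."""


class GridMismatchError(CvrBhError):
    """Arrays expected on the same voxel grid have different shapes."""


class DelayRangeWarning(UserWarning):
    """Optimal delay landed on a search boundary; the true delay may lie outside."""


class EmptyMaskWarning(UserWarning):
    """A mask operation produced or consumed an empty mask."""
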