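"""Exception hierarchy shared across the package."""


class RoldsisError(Exception):
    """Base class for package-specific errors."""


class RankDeficiencyError(RoldsisError, ValueError):
    """Observations are collinear/duplicated: the centered matrix has rank < M-1."""


class SingularSystemError(RoldsisError, ValueError):
    """The even-determined M x M system is numerically singular."""


class DimensionMismatchError(RoldsisError, ValueError):
    """A vector or matrix does not have the expected dimensions."""


class LayoutError(RoldsisError, ValueError):
    """Wavelet layout inconsistent with the requested operation."""
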