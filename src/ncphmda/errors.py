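"""Exception types raised across the package."""


class NcphmdaError(Exception):
    """Base class for all package-specific errors."""


class EdgeListFormatError(NcphmdaError, ValueError):
    """An association/symptom file has fewer columns than required or bad values."""


class EmptyEdgeListError(NcphmdaError, ValueError):
    """An edge list contains no edges after comment stripping."""


class DegenerateNetworkError(NcphmdaError, ValueError):
    """All interaction profiles are zero, so the Gaussian kernel bandwidth is undefined."""


class AlignmentError(NcphmdaError, ValueError):
    """Matrix shapes or label sets do not line up between two objects."""
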