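"""Exception hierarchy shared across the package."""


class WtpeError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabetError(WtpeError, ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class CoordinateError(WtpeError, ValueError):
    """Interval or position falls outside the reference it refers to."""


class DesignError(WtpeError, ValueError):
    """A pegRNA or pair design request is geometrically impossible."""


class ReferenceMismatchError(WtpeError, ValueError):
    """A homology arm does not match the reference it must anneal to."""


class ConfigError(WtpeError, ValueError):
    """Malformed user configuration (duplicate barcodes, bad mixture, ...)."""


class EmptyTableError(WtpeError, ValueError):
    """No retained reads: frequencies are undefined."""


class InsufficientDataError(WtpeError, ValueError):
    """Too few points to fit (standard curve needs >= 3 dilutions)."""


class UndefinedEfficiencyError(WtpeError, ValueError):
    """Efficiency is 0/0 (e.g. both gel bands have zero greyscale)."""
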