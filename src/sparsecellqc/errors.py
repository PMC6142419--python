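"""Exception types shared across the package."""


class SparseCellQCError(Exception):
    """Base class for package errors."""


class UndefinedStatisticError(SparseCellQCError):
    """A statistic is mathematically undefined for the given input.

    Raised instead of returning 0 or NaN so callers cannot silently
    propagate a meaningless value (e.g. VAF with zero allelic depth,
    SNR with zero dispersion, a mismatch fraction over an empty site
    universe).
    """


class FitConvergenceError(SparseCellQCError):
    """A curve fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(SparseCellQCError):
    """Invalid configuration (overlapping CNA segments, bad cell counts, ...)."""
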