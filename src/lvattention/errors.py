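"""Exception types shared across the package."""


class LVAttentionError(Exception):
    """Base class for all package-specific errors."""


class TrendsParseError(LVAttentionError, ValueError):
    """Malformed input CSV: bad cell, missing/duplicate dates, broken cadence."""


class InsufficientDataError(LVAttentionError, ValueError):
    """Too few observations to fit any model."""


class AlignmentError(LVAttentionError, ValueError):
    """Objects that must share a time axis do not."""


class FitRankError(LVAttentionError, ValueError):
    """Rank-deficient least-squares design (too few or degenerate samples)."""


class IntegrationError(LVAttentionError, RuntimeError):
    """Numerical ODE integration failed."""
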