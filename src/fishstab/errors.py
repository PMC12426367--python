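"""Typed exceptions shared across the package.

Degenerate statistical conditions (zero variance, perfect compensation,
zero mean) raise errors rather than returning infinities, so that batch
pipelines can catch them and record the affected region-year as missing.
"""

from __future__ import annotations


class FishstabError(Exception):
    """Base class for all package errors."""


class ValidationError(FishstabError):
    """Raised when input records violate the tidy-long schema."""


class IncompletePanelError(FishstabError):
    """Raised when a species x month matrix has missing cells.

    Absence of a row is not zero: gaps must be resolved upstream.
    """

    def __init__(self, message: str, gaps: list[tuple[str, int]] | None = None):
        super().__init__(message)
        self.gaps = gaps or []


class DegenerateSeriesError(FishstabError):
    """A stability or asynchrony quantity is undefined for this input.

    ``code`` is one of:

    - ``"zero-variance"``: every species SD is zero (or the aggregate
      series is constant) so inverse-CV stability is infinite;
    - ``"perfect-compensation"``: the summed series is exactly constant
      while individual species fluctuate (sigma_R = 0);
    - ``"zero-mean"``: the temporal mean of the aggregate is zero;
    - ``"zero-denominator"``: a ratio index has an empty or all-zero
      denominator window;
    - ``"undefined-timing"``: harvest timing requested for a species-year
      with zero total harvest.
    """

    def __init__(self, message: str, code: str):
        super().__init__(message)
        self.code = code


class CollinearityError(FishstabError):
    """Raised when a sub-model design matrix is rank deficient."""


class NonStationaryError(FishstabError):
    """Raised when an autoregressive error estimate leaves the stationary region."""
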