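"""Exception hierarchy shared by all pipeline stages."""


class ProfilerError(Exception):
    """Base class for all errors raised by this package."""


class NonRetainedSoluteError(ProfilerError):
    """Retention time does not exceed the dead time: no capacity factor exists."""


class InvalidDeadTimeError(ProfilerError):
    """Dead time t0 must be strictly positive."""


class InsufficientDataError(ProfilerError):
    """Too few (or degenerate) observations for the requested fit."""


class InvalidProfileError(ProfilerError):
    """Concentration-time profile violates its invariants (ordering, signs)."""


class UndefinedBioavailabilityError(ProfilerError):
    """IV exposure is zero; the oral/IV ratio is undefined."""


class UnknownElementError(ProfilerError):
    """Element symbol missing from the active radii/mass table."""


class NoTopologyError(ProfilerError):
    """Bond information required but absent and not inferrable."""


class EmptyEnsembleError(ProfilerError):
    """An ensemble-level statistic was requested for zero frames."""


class InvalidBinningError(ProfilerError):
    """Histogram bin widths must be strictly positive."""


class LabelMismatchError(ProfilerError):
    """Paired summaries refer to different compounds."""


class InvalidValueError(ProfilerError):
    """Scalar input outside its physical domain (e.g. negative F%)."""


class InvalidDenominatorError(ProfilerError):
    """Ratio denominator is zero or negative."""


class FormatParseError(ProfilerError):
    """Malformed structure file; message carries the offending line number."""


class DependencyError(ProfilerError):
    """A requested pipeline stage is missing an upstream input."""
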