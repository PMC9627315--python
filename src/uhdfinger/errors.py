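"""Exception types shared across the pipeline."""


class UhdFingerError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(UhdFingerError, ValueError):
    """A parameter violates a precondition (non-positive pitch, band outside Nyquist, ...)."""


class InvalidEventError(UhdFingerError, ValueError):
    """An event table contains a trial_type the generator or epocher does not know."""


class InvalidDataError(UhdFingerError, ValueError):
    """Input data cannot be processed (class imbalance, missing channels, ...)."""


class DegenerateDataError(UhdFingerError, ValueError):
    """Data are degenerate for the requested statistic (all channels bad, all-zero differences, ...)."""
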