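"""Exception hierarchy shared across the pipeline."""


class BurstError(Exception):
    """Base class for all pipeline errors."""


class FormatError(BurstError):
    """A file is missing required columns or is otherwise malformed."""


class SamplingError(BurstError):
    """A time series is not uniformly sampled within tolerance."""


class ValidationError(BurstError):
    """Input values violate a domain invariant (mass <= 0, theta >= 90, ...)."""


class InsufficientDataError(BurstError):
    """Too few frames, trials, or replicates for the requested operation."""


class NoStrideError(BurstError):
    """No loaded interval could be detected in a force trace."""


class ConvergenceError(BurstError):
    """An iterative fit failed to converge; carries diagnostics in args."""
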