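"""Exception types shared across the package."""


class ImotivError(Exception):
    """Base class for all package errors."""


class InvalidDistributionError(ImotivError, ValueError):
    """A vector or matrix fails a stochasticity or non-negativity invariant."""


class AbsoluteContinuityError(ImotivError, ValueError):
    """KL divergence requested where p > 0 but q = 0."""


class ConfigurationError(ImotivError, ValueError):
    """A model or environment specification is internally inconsistent."""


class EnumerationCapError(ImotivError, ValueError):
    """Exhaustive policy enumeration would exceed the configured cap."""


class InferenceError(ImotivError, ValueError):
    """Inference is impossible (e.g. an observation with zero marginal likelihood)."""
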