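"""Package-wide exception types."""


class InvalidParameterError(ValueError):
    """A model or config parameter violates its documented domain."""


class NoSignalError(RuntimeError):
    """An image carries no thresholdable signal (e.g. flat raster).

    Callers counting particles treat this as a zero count.
    """


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested for a constant vector."""
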