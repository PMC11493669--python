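"""Package-wide exception types."""


class EcgcsError(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(EcgcsError, ValueError):
    """Incompatible array shapes (e.g. operator vs. signal length)."""


class CoverageError(EcgcsError, ValueError):
    """A sample of the signal is not covered by any block estimate."""


class DivergenceError(EcgcsError, RuntimeError):
    """An AMP iterate became non-finite."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(message or f"non-finite AMP state at iteration {iteration}")
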