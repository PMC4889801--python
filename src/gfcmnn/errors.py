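"""Exception types shared across the package."""


class GFCMNNError(Exception):
    """Base class for all package-specific errors."""


class InvalidTripleError(GFCMNNError, ValueError):
    """An intuitionistic fuzzy triple violates its range or sum constraints."""


class InvalidParamsError(GFCMNNError, ValueError):
    """Score-function or network configuration parameters are out of range."""


class DimensionError(GFCMNNError, ValueError):
    """Array arguments have inconsistent shapes or lengths."""


class ParseError(GFCMNNError, ValueError):
    """A dataset file is malformed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateGradientError(GFCMNNError, ValueError):
    """A learning-rate formula was evaluated at a zero gradient factor."""


class DivergenceError(GFCMNNError, RuntimeError):
    """Training cost exceeded the divergence guard."""

    def __init__(self, epoch: int, cost: float):
        self.epoch = epoch
        self.cost = cost
        super().__init__(
            f"training diverged at epoch {epoch}: epoch cost {cost:.3e} "
            "exceeds the divergence guard (1e6)"
        )


class FixtureIntegrityError(GFCMNNError, RuntimeError):
    """Packaged fixture data failed its integrity checks."""


class InvalidSpecError(GFCMNNError, ValueError):
    """A synthetic-data specification cannot be satisfied."""
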