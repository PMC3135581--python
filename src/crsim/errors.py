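"""Named failure modes shared across the package.

Every precondition breach raises one of these types so callers (and the CLI)
can distinguish bad input from bugs.
"""


class CrsimError(Exception):
    """Base class for all named failures."""


class ValidationError(CrsimError):
    """A dataset row or field violates the competing-risks data contract."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class EmptyDatasetError(CrsimError):
    """An operation that needs at least one subject received none."""


class NoEventsError(CrsimError):
    """A law or estimate is undefined because the data contain no events."""


class InadmissibleIncrementError(CrsimError):
    """A pooled discrete-hazard increment exceeds 1, so no probability law
    exists for the requested transformation/effect combination."""

    def __init__(self, time: float, increment: float):
        self.time = time
        self.increment = increment
        super().__init__(
            f"pooled hazard increment {increment:.6g} > 1 at time {time:.6g}; "
            "the transformed/scaled hazards do not define a probability law"
        )


class ConvergenceError(CrsimError):
    """A fit failed to converge (e.g. complete separation of event times)."""


class EmptyWindowError(CrsimError):
    """A time-window restriction left no support points to compare."""


class UnspentCensoringMassWarning(UserWarning):
    """The censoring survival curve does not spend all its probability mass;
    the remainder is placed just after the largest observed time."""
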