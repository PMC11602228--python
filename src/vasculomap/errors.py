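"""Exception hierarchy shared by all pipeline stages."""

from __future__ import annotations


class VasculomapError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(VasculomapError):
    """A malformed line in a hierarchy table or vascular-path file.

    Carries the 1-based line number when available.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CycleError(VasculomapError):
    """A directed cycle reachable from a tile root.

    ``cycle`` lists the node ids forming the loop.
    """

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("cycle reachable from a tile root: " + " -> ".join(self.cycle))


class ConfigError(VasculomapError):
    """An invalid configuration value (out-of-range parameter, bad plan)."""


class CapacityError(VasculomapError):
    """A fixed treemap grid too small for a node's children."""


class AmbiguityError(VasculomapError):
    """A vascular segment id claimed by more than one tile."""


class GenerationError(VasculomapError):
    """The synthetic generator cannot satisfy its configuration."""


class RoutingError(VasculomapError):
    """An edge cannot be routed through the designated channels."""


class StageError(VasculomapError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
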