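"""Exception hierarchy for mdpost.

Every error raised by the library derives from :class:`MdpostError` so that
callers (and the pipeline driver) can catch analysis failures without
swallowing programming errors.
"""


class MdpostError(Exception):
    """Base class for all mdpost errors."""


class InvalidSpecError(MdpostError, ValueError):
    """A synthetic-data specification violates its invariants."""


class ParseError(MdpostError, ValueError):
    """A file could not be parsed; the message names the offending line/frame."""


class StructuralError(MdpostError, ValueError):
    """File structure inconsistent with the topology (e.g. atom-count mismatch)."""


class SelectionError(MdpostError, ValueError):
    """An atom selection is empty, out of range, or unknown."""


class DegenerateGeometryError(MdpostError, ValueError):
    """Geometry insufficient for the requested operation (collinear, < 3 atoms...)."""


class UndefinedStatisticError(MdpostError, ValueError):
    """A statistic is undefined for the given input (zero variance, one frame...)."""


class ParameterError(MdpostError, ValueError):
    """A physical/numerical parameter is missing or out of its valid range."""


class SingularityError(MdpostError, ValueError):
    """Overlapping atoms make a pairwise energy singular."""


class ConvergenceError(MdpostError, RuntimeError):
    """An iterative solver failed to converge; message reports the residual."""


class InsufficientPaddingError(MdpostError, ValueError):
    """The PB solute touches the grid boundary."""


class InfeasibleScheduleError(MdpostError, ValueError):
    """A contact schedule cannot be co-satisfied."""


class UnreachableError(MdpostError, ValueError):
    """Source and sink lie in different network components."""


class ConfigError(MdpostError, ValueError):
    """Pipeline configuration invalid or incomplete."""


class StageError(MdpostError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
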