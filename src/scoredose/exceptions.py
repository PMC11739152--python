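"""Exception hierarchy shared across the package.

All errors derive from :class:`ScoreDoseError` so callers can catch the
package's failures with one clause; the leaf classes mirror the kinds of
contract violation the library checks for (bad parameters, mismatched
shapes, degenerate schedule times, broken data, training divergence).
"""


class ScoreDoseError(Exception):
    """Base class for all scoredose errors."""


class ParameterError(ScoreDoseError, ValueError):
    """A configuration or function parameter violates its contract."""


class ShapeError(ScoreDoseError, ValueError):
    """Array arguments have incompatible shapes or channel counts."""


class RangeError(ScoreDoseError, ValueError):
    """A time, index, or coordinate falls outside its valid range."""


class ScheduleError(ScoreDoseError, ValueError):
    """A noise schedule is inconsistent with the requested operation."""


class DegenerateTimeError(ScoreDoseError, ZeroDivisionError):
    """The perturbation kernel has zero variance at the requested time."""


class DataError(ScoreDoseError, ValueError):
    """A dataset or batch is missing required channels or cases."""


class DivergenceError(ScoreDoseError, RuntimeError):
    """Training produced a non-finite loss."""


class ConfigError(ScoreDoseError, ValueError):
    """A run/model configuration is internally inconsistent."""
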