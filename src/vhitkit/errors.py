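"""Exception hierarchy.

Every error raised by vhitkit derives from :class:`VhitError`, so callers can
catch one type at a pipeline boundary while tests assert on the specific
subclass.
"""


class VhitError(Exception):
    """Base class for all vhitkit errors."""


class BoundViolationError(VhitError):
    """Impulse kinematics exceed the acceleration or displacement bound."""


class CapacityError(VhitError):
    """Requested impulses do not fit into the requested trace duration."""


class TraceFormatError(VhitError):
    """A velocity trace violates its format contract (columns, uniform
    sampling, finiteness)."""


class GainWindowError(VhitError):
    """The fixed gain window is degenerate or falls outside the trace."""


class InsufficientImpulsesError(VhitError):
    """Fewer than the required number of valid impulses in a direction."""


class UndefinedAsymmetryError(VhitError):
    """Asymmetry index undefined because the gain sum is non-positive."""


class DegenerateVarianceError(VhitError):
    """An ANOVA error term is (numerically) zero; F is undefined."""


class ValidationError(VhitError):
    """A record, answer or table failed schema/vocabulary validation."""


class ConstantInputError(VhitError):
    """Correlation requested on a constant vector."""


class PowerSearchError(VhitError):
    """Sample-size search exhausted its cap without reaching target power."""


class ConfigError(VhitError):
    """A run configuration contains unknown keys or invalid values."""
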