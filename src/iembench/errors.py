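"""Typed exceptions shared across the package.

The CLI maps these onto its exit-code contract: validation problems
(:class:`InvalidParameterError`, :class:`ConfigError`) exit 2, numerical
problems (:class:`RankDeficiencyError`, :class:`DegenerateDenominatorError`)
exit 3.
"""


class IEMBenchError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IEMBenchError, ValueError):
    """A parameter violates a documented precondition."""


class ConfigError(IEMBenchError, ValueError):
    """A run configuration is malformed; message names the field path."""


class ShapeMismatchError(IEMBenchError, ValueError):
    """Array dimensions are inconsistent between operands."""


class RankDeficiencyError(IEMBenchError, ValueError):
    """A matrix that must be full rank (or invertible) is not; message
    names the deficient dimension."""


class LeakageError(IEMBenchError, ValueError):
    """Training and test partitions overlap."""


class BasisKindError(IEMBenchError, TypeError):
    """An operation requires a unimodal (cosine or delta) basis but was
    given a transformed one."""


class DegenerateDenominatorError(IEMBenchError, ZeroDivisionError):
    """A ratio's denominator is zero or non-positive where positivity is
    required."""
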