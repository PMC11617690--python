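"""Exception hierarchy.

Three broad classes mirror the CLI exit codes: configuration problems (exit 2),
data problems (exit 3) and numerical problems (exit 4).
"""


class CopotError(Exception):
    """Base class for all package errors."""


class ConfigError(CopotError):
    """Invalid configuration, spec file, or argument combination."""


class DataError(CopotError):
    """Input data cannot support the requested computation."""


class InsufficientDataError(DataError):
    """Too few observations (e.g. fewer exceedances than the minimum)."""


class NoOverlapError(DataError):
    """Two trajectories share no frame."""


class EmptyRegionError(DataError):
    """No observation falls in the requested region (e.g. below d0)."""


class NumericalError(CopotError):
    """Numerical failure: bad parameter domain, non-convergence, out-of-support."""


class ParameterDomainError(NumericalError):
    """Parameter outside its admissible domain."""


class FitError(NumericalError):
    """Optimizer failed to converge or the sample is degenerate."""


class UnsupportedDependenceError(NumericalError):
    """The copula family cannot represent the sample's rank correlation.

    Gumbel and Clayton copulas only represent positive dependence; for a
    negative sample tau, apply the decreasing-transform adjustment (negate the
    severity margin) and fit the copula to the transformed pair.
    """


class OutOfRegionError(NumericalError):
    """Query point outside the region the restricted-measure model covers."""


class ExtrapolationError(NumericalError):
    """Conditioning event has probability zero under the fitted tail."""
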