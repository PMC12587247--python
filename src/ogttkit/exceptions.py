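"""Exception hierarchy for ogttkit.

All package errors derive from :class:`OgttError` so callers can catch one
base class; the subclasses distinguish schema problems in input files from
physiologically invalid values, protocol misconfiguration, and numerical
failures during estimation.
"""


class OgttError(Exception):
    """Base class for all ogttkit errors."""


class SchemaError(OgttError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(OgttError):
    """A value violates a domain invariant (non-monotone time, negative
    concentration, tracer-to-tracee ratio outside [0, 1), ...)."""


class ProtocolError(OgttError):
    """The subject protocol is incomplete or inconsistent with the data."""


class InsufficientBasalError(ValidationError):
    """Fewer than the required number of basal (t <= 0) samples."""


class GridMismatchError(OgttError):
    """Two per-sample series are not defined on the same time grid."""


class DivisionGuardError(OgttError):
    """A tracer enrichment hit zero or below where a division is required."""


class EstimationError(OgttError):
    """Numerical failure during parameter estimation."""


class InitializationError(EstimationError):
    """The greedy initializer found no finite cost anywhere on its lattice."""


class SingularityError(EstimationError):
    """The sensitivity matrix is rank deficient; covariance is undefined."""


class ScenarioError(OgttError):
    """A synthetic-data scenario is inconsistent (truth outside fitting
    bounds, negative noise, ...)."""
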