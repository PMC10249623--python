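"""Exception hierarchy.

All package-specific errors derive from :class:`KawcycleError` so callers
can catch everything from this package with a single except clause.
Validation problems (bad geometry, bad schema) additionally derive from
``ValueError`` to behave well in generic code.
"""


class KawcycleError(Exception):
    """Base class for all errors raised by kawcycle."""


class InvalidInputError(KawcycleError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class InvalidGeometryError(InvalidInputError):
    """Phase volumes describe an impossible or degenerate vial geometry."""


class InfeasibleMassBalanceError(KawcycleError):
    """Measured concentrations imply more mass in a phase than was spiked."""


class InsufficientReplicatesError(KawcycleError):
    """Fewer than two replicate measurements."""


class NoDataError(KawcycleError):
    """An operation that requires at least one value received none."""


class UnderDeterminedError(KawcycleError):
    """Not enough distinct design points to identify the parameters."""


class ConvergenceError(KawcycleError):
    """Iterative fit failed to converge; ``.fit`` carries the best iterate."""

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit


class InconsistentPairError(KawcycleError):
    """An (accurate, apparent) pair with apparent > accurate value."""


class InconsistentSeriesError(KawcycleError):
    """Homologue series with mixed units or quantities cannot be pooled."""


class NoOverlapError(KawcycleError):
    """Prediction and experimental tables share no compound."""


class SchemaError(KawcycleError, ValueError):
    """A table fails schema validation; message names row and column."""


class MissingValueError(KawcycleError, LookupError):
    """A requested compound or quantity is absent from a value table."""
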