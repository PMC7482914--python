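"""Exception types shared across the package."""


class NetattackError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NetattackError, ValueError):
    """An input file violates the expected column schema or references
    undeclared actors."""


class ValidationError(NetattackError, ValueError):
    """A domain object violates one of its invariants (bipartite
    constraint, negative reputation, wave inconsistency, ...)."""


class UnknownActorError(NetattackError, KeyError):
    """An actor id is not present in the network."""


class ContractError(NetattackError, ValueError):
    """An operation was called with arguments violating its contract
    (dimension mismatch, non-positive rate, unknown strategy, ...)."""


class UndefinedMetricError(NetattackError, ArithmeticError):
    """A metric is undefined on this input (e.g. a Pearson correlation
    over a constant degree sequence).  Deliberately distinct from
    returning 0: callers that tabulate metrics record a missing value."""


class UnfittableError(NetattackError, ValueError):
    """A distributional fit is impossible on this input (degenerate or
    too-small sample)."""


class IllConditionedError(NetattackError, ArithmeticError):
    """The moment sensitivity matrix is numerically singular; carries the
    name of the offending effect."""

    def __init__(self, effect_name: str, message: str | None = None):
        self.effect_name = effect_name
        super().__init__(message or f"sensitivity matrix is singular in direction of effect {effect_name!r}")
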