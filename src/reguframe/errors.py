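"""Exception hierarchy shared across the pipeline stages."""


class ReguframeError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ReguframeError):
    """A configuration violates its invariants (bad reliabilities,
    infeasible standardized paths, probabilities not summing to one...)."""


class SchemaError(ReguframeError):
    """Tabular input is missing required columns or has the wrong types."""


class DataError(ReguframeError):
    """Data are structurally valid but unusable (e.g. a non-positive-definite
    sample covariance)."""


class DegenerateVariableError(ReguframeError):
    """A variable has too few distinct values to be tertile-coded."""


class ImpossibleEvidenceError(ReguframeError):
    """Evidence has zero probability under the network."""


class ContractError(ReguframeError):
    """An operation was called outside its preconditions (illegal move,
    terminal state...)."""


class ComplexityError(ReguframeError):
    """A requested computation exceeds the tractable size bounds."""
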