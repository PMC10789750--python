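"""Exception hierarchy shared across the package."""


class LsfRegioError(Exception):
    """Base class for all package errors."""


class ParseError(LsfRegioError):
    """A SMILES string could not be parsed."""


class FeaturizationError(LsfRegioError):
    """An atom falls outside the configured feature vocabulary."""


class DegradedProductError(LsfRegioError):
    """The starting material is not a subgraph of the product.

    Raised when no element/bond-compatible embedding exists, e.g. for
    degradation byproducts whose core has fragmented; such records need
    manual reaction-center elucidation.
    """

    def __init__(self, message: str, record_id: str | None = None):
        super().__init__(message)
        self.record_id = record_id


class DomainError(LsfRegioError):
    """An operation was applied to an atom type it is not defined for."""


class UnknownConditionError(LsfRegioError):
    """A condition token is absent from the vocabulary (strict mode)."""


class SplitError(LsfRegioError):
    """A scaffold split cannot satisfy the requested fractions."""


class FormatError(LsfRegioError):
    """An input table has too many malformed rows to trust."""


class ModelError(LsfRegioError):
    """Shape or fingerprint mismatch in the neural network."""


class LossError(LsfRegioError):
    """Loss inputs are outside their valid domain."""


class ConfigError(LsfRegioError):
    """An invalid configuration value."""


class TrainingError(LsfRegioError):
    """Training diverged or its inputs are degenerate."""


class TransferError(ModelError):
    """Checkpoint trunk is incompatible with the current architecture."""


class UndefinedMetricError(LsfRegioError):
    """A metric is undefined for the given inputs (e.g. one-class AUROC)."""


class ChargeTableError(LsfRegioError):
    """Per-atom charges do not sum to the stated molecular charge."""


class EmptyPredictionError(LsfRegioError):
    """No eligible site exists to predict on."""
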