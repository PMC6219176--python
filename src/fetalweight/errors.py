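"""Exception hierarchy shared across the package."""


class FetalWeightError(Exception):
    """Base class for all package-specific errors."""


class LookupFailure(FetalWeightError, KeyError):
    """Unknown standard, biometry or model identifier."""


class GARangeError(FetalWeightError, ValueError):
    """Gestational age outside a growth standard's validated range."""


class ValidationFailure(FetalWeightError, ValueError):
    """A record or argument violates a documented contract."""


class MissingPredictorError(ValidationFailure):
    """A weight model's required predictor is absent from the record."""

    def __init__(self, model_id: str, missing: list[str]):
        self.model_id = model_id
        self.missing = sorted(missing)
        super().__init__(
            f"model '{model_id}' is missing required predictor(s): "
            + ", ".join(self.missing)
        )


class DegenerateInputError(FetalWeightError, ValueError):
    """Input with no usable variation (constant column, zero variance)."""


class CollinearityError(FetalWeightError, ValueError):
    """Design matrix is rank deficient."""

    def __init__(self, dependent: list[str]):
        self.dependent = list(dependent)
        super().__init__(
            "design matrix is rank deficient; linearly dependent column(s): "
            + ", ".join(self.dependent)
        )


class ConfigurationError(FetalWeightError, ValueError):
    """Generator or calibration configuration is infeasible."""
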