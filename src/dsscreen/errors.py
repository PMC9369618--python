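"""Exception hierarchy shared across the pipeline.

Config/schema problems exit a CLI run with code 2, data problems with
code 3; library callers catch the classes directly.
"""


class DsScreenError(Exception):
    """Base class for all package errors."""


class SchemaError(DsScreenError):
    """An input table or matrix does not have the expected columns."""


class ValidationError(DsScreenError):
    """A value inside an otherwise well-formed input is not allowed."""


class ContractError(DsScreenError):
    """A caller violated a documented precondition."""


class ParameterError(DsScreenError):
    """A numeric parameter is outside its admissible range."""


class FeaturizationError(DsScreenError):
    """One or more SMILES could not be interpreted during featurization."""

    def __init__(self, bad_ids):
        self.bad_ids = list(bad_ids)
        super().__init__(f"unparseable SMILES for records: {', '.join(self.bad_ids)}")


class DegenerateMatrixError(DsScreenError):
    """Feature cleaning removed every column."""


class StratificationError(DsScreenError):
    """A class has too few members for stratified cross-validation."""


class TotalConflictError(DsScreenError):
    """Two mass vectors are in total conflict (Kc = 1); use the fallback path."""


class UndefinedKappaError(DsScreenError):
    """Cohen's kappa is undefined because expected agreement is 1."""


class ConfigError(DsScreenError):
    """A run configuration failed validation before any computation."""
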