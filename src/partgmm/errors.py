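"""Exception hierarchy for partgmm."""


class PartGmmError(Exception):
    """Base class for all partgmm errors."""


class ConfigurationError(PartGmmError):
    """A column mapping or run configuration is malformed."""


class DataError(PartGmmError):
    """Input data violate a contract (non-binary outcome, missing values, ...)."""


class BalanceError(DataError):
    """A subject does not have exactly one record per wave."""


class ParameterError(PartGmmError):
    """An argument is out of its valid range or has the wrong shape."""


class DegenerateFitError(PartGmmError):
    """A fitted mean reached 0 or 1, so standardized residuals are undefined."""


class SeparationError(PartGmmError):
    """The working-independence logistic fit diverged (complete separation)."""


class ConvergenceError(PartGmmError):
    """The GMM optimizer did not converge within its iteration budget."""

    def __init__(self, message, last_beta=None, diagnostics=None):
        super().__init__(message)
        self.last_beta = last_beta
        self.diagnostics = diagnostics or {}
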