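"""Exception hierarchy for fixsim.

All errors derive from :class:`FixsimError` so callers can catch the package's
failures with a single except clause; the subclasses mirror the kinds of
invalid input the library distinguishes (parameters, covariates, regimens,
configuration, dataset schema).
"""


class FixsimError(Exception):
    """Base class for all fixsim errors."""


class InvalidParameterError(FixsimError, ValueError):
    """A pharmacokinetic parameter violates its positivity constraints."""


class InvalidCovariateError(FixsimError, ValueError):
    """A patient covariate (weight, weight-adjusted dose) is out of domain."""


class InvalidRegimenError(FixsimError, ValueError):
    """A dosing regimen is ill-formed (non-positive interval, dose, ...)."""


class ConfigError(FixsimError, ValueError):
    """A configuration block (variances, calibration, replicate counts) is invalid."""


class DatasetSchemaError(FixsimError, ValueError):
    """A tabular dataset violates the required long-format schema."""
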