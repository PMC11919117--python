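"""Exception hierarchy for mrmediate.

All failures a caller can reasonably act on raise a subclass of
:class:`MRMediateError`; programming errors raise builtins.
"""


class MRMediateError(Exception):
    """Base class for all mrmediate errors."""


class ConfigurationError(MRMediateError):
    """Invalid configuration: missing columns, bad parameter values."""


class EmptyInputError(MRMediateError):
    """An input table contained no valid rows."""


class EmptySelectionError(MRMediateError):
    """No variant survived instrument selection for a trait."""


class InsufficientInstrumentsError(MRMediateError):
    """Fewer instruments than the estimator's minimum."""


class DegenerateInstrumentError(MRMediateError):
    """An instrument with zero exposure effect was used in a ratio."""


class CollinearityError(MRMediateError):
    """The multivariable exposure-effect matrix is rank deficient."""


class CannotCorrectError(MRMediateError):
    """Outlier correction would remove every instrument."""


class UnitError(MRMediateError):
    """An operation valid only on one effect scale was called on another."""
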