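"""Exception hierarchy for thetanav.

All package-raised errors derive from :class:`ThetaNavError` so callers can
catch the package's failures without catching programming errors.
"""


class ThetaNavError(Exception):
    """Base class for all thetanav errors."""


class FormatError(ThetaNavError):
    """An input file does not have the expected tabular structure."""


class ValidationError(ThetaNavError):
    """Input data violates a documented invariant (e.g. non-monotone time)."""


class DegenerateInputError(ThetaNavError):
    """The requested transform or statistic is undefined for this input."""


class ConfigError(ThetaNavError):
    """A pipeline configuration entry is missing or unrecognised."""


class FitError(ThetaNavError):
    """A model fit cannot be carried out on the given data."""


class UndefinedMetricError(ThetaNavError):
    """A performance metric is undefined (e.g. AUROC with one class)."""
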