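"""Exception hierarchy shared by all phenoplate modules."""


class PhenoplateError(Exception):
    """Base class for all phenoplate errors."""


class FormatError(PhenoplateError):
    """Malformed input file or table (bad well address, duplicate well, non-numeric cell)."""


class ValidationError(PhenoplateError):
    """Input parsed but violates a domain invariant or precondition."""


class FitError(PhenoplateError):
    """A regression could not be performed or did not converge."""


class QualityError(PhenoplateError):
    """Data present but below a required quality threshold (e.g. no window meets min r^2)."""


class ConfigError(PhenoplateError):
    """Invalid configuration (empty limits table, infeasible hyperparameters, overflow)."""
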