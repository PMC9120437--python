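"""Exception hierarchy shared across the pipeline stages."""


class DynawassError(Exception):
    """Base class for all package errors."""


class FormatError(DynawassError):
    """A file could not be interpreted as the expected format."""


class ConfigurationError(DynawassError):
    """Missing or inconsistent user configuration."""


class PreconditionError(DynawassError):
    """An operation was called on inputs that violate its contract."""


class DegenerateGeometryError(DynawassError):
    """Too few or collinear fit atoms for a rigid-body superposition."""


class NoBindingSiteError(DynawassError):
    """No residue exceeded the contact-activity threshold in any run."""


class DegenerateDistributionError(DynawassError):
    """A statistic is undefined because the sample is constant."""


class TrainingDivergenceError(DynawassError):
    """Critic training produced a non-finite loss."""
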