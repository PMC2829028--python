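"""Exception types shared across the package."""


class AonsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AonsimError):
    """A parameter set or configuration file is invalid.

    The message always names the offending field or key.
    """


class UnknownOrganError(AonsimError, KeyError):
    """An organ id was not found in the plant topology."""


class DegenerateBaselineError(AonsimError):
    """The similarity degree is undefined because the mutant baseline does
    not out-nodulate the wild-type baseline (n_nt <= n_br)."""
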