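"""Exception hierarchy for configuration and numerical failures."""


class PrimeSimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PrimeSimError):
    """A model configuration is incomplete or internally inconsistent."""


class UnitError(ConfigurationError):
    """A quantity's unit does not match the component registry."""


class DuplicateParameterError(ConfigurationError):
    """More than one parameter record covers the same (exposure, cause) pair."""


class ChainingError(ConfigurationError):
    """A mediation parameter and a relative-risk parameter do not chain."""


class ParseError(PrimeSimError):
    """A data file could not be parsed; the message names the offending line."""


class FeasibilityError(PrimeSimError):
    """Requested moments are not attainable under the chosen distribution family."""


class NumericError(PrimeSimError):
    """A numerical routine failed to converge; the message carries diagnostics."""
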