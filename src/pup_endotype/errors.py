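"""Exception hierarchy shared across the package.

``InputError`` covers malformed or physically unusable inputs (CLI exit
code 2); ``AnalysisError`` covers failures of the analysis itself on
otherwise valid inputs (CLI exit code 3).
"""


class PupError(Exception):
    """Base class for all package-specific errors."""


class InputError(PupError, ValueError):
    """Unusable input: bad file, bad schema, bad configuration."""


class AnalysisError(PupError, RuntimeError):
    """The analysis cannot proceed on these (valid) inputs."""


class NoBreathsError(InputError):
    """No inspiratory onsets could be found in the flow signal."""


class FlatSignalError(AnalysisError):
    """Local eupnea baseline is zero; ventilation cannot be normalized."""


class InsufficientDataError(AnalysisError):
    """Too few unobstructed breaths (or windows) to fit the drive model."""


class UnstableConfigError(InputError):
    """Simulator configuration whose drive diverges without bound."""
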