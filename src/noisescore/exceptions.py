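"""Exception hierarchy for noisescore."""


class NoiseScoreError(Exception):
    """Base class for all package errors."""


class InsufficientDataError(NoiseScoreError):
    """Too few frames, levels, samples or annotations to proceed."""


class FitFailureError(NoiseScoreError):
    """The photon-transfer regression produced a non-physical model."""


class ConfigurationError(NoiseScoreError):
    """A required configuration element is missing or inconsistent."""


class ZeroUncertaintyError(NoiseScoreError):
    """A standard score was requested with sigma_raw == 0."""


class PackingError(NoiseScoreError):
    """A phantom scene could not be packed within the retry budget."""
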