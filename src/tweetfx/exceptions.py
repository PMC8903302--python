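"""Exception hierarchy shared across the package."""


class TweetfxError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TweetfxError, ValueError):
    """A configuration field is invalid; the message names the field."""


class DataError(TweetfxError, ValueError):
    """Input data violates a contract (missing metadata, non-finite value, ...)."""


class EstimationError(TweetfxError, RuntimeError):
    """An estimator cannot be computed on the data it was given."""
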