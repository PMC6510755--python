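"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A spec, profile or config object violates its invariants."""


class EmptyInputError(ValueError):
    """An operation received an empty volume, image list or cohort."""


class PredictionError(RuntimeError):
    """Model used incorrectly (e.g. prediction from an untrained network)."""
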