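"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid configuration value (non-positive count, probability outside [0, 1], ...)."""


class ContractError(ValueError):
    """A violated call contract (unsorted input, negative delta, shape mismatch, ...)."""


class FeatureError(KeyError):
    """A feature id requested that the fitted normalizer / feature list does not know."""
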