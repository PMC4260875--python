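"""Exception hierarchy for tierplan."""


class TierplanError(Exception):
    """Base class for all tierplan errors."""


class SchemaError(TierplanError):
    """A required column, field or config key is missing or malformed."""


class ValidationError(TierplanError):
    """A value violates a domain invariant (range, sign, enum membership)."""


class IntegrityError(TierplanError):
    """A registry-level consistency violation, e.g. duplicate ids."""


class ConfigError(TierplanError):
    """An invalid or internally inconsistent configuration."""
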