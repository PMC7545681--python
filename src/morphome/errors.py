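"""Exception types shared across the package."""


class MorphomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MorphomeError, ValueError):
    """A delimited-text input does not have the expected layout."""


class IntegrityError(MorphomeError, ValueError):
    """Input rows violate a domain invariant (duplicate keys, bad enum values)."""


class FitError(MorphomeError, RuntimeError):
    """A model fit could not be completed (singular information, no events)."""
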