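"""Exception hierarchy.

All package-specific failures derive from :class:`GaitmosError` so callers can
catch one base class; subclasses distinguish malformed files, inconsistent
in-memory data, event-detection failures and bad configuration.
"""


class GaitmosError(Exception):
    """Base class for all gaitmos errors."""


class SchemaError(GaitmosError):
    """A file is missing required columns / markers; message names them."""


class DataError(GaitmosError):
    """Data values violate an invariant (non-monotonic time, bad shape...)."""


class DetectionError(GaitmosError):
    """Gait-event detection failed (no peaks, alternation violated)."""


class ConfigurationError(GaitmosError):
    """Inconsistent configuration or dimensions."""
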