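"""Exception types shared across the engine."""


class AuditestError(Exception):
    """Base class for all engine errors."""


class UndefinedLevelError(AuditestError, ValueError):
    """A level/SNR operation was asked to act on a zero-energy signal."""


class HeadroomError(AuditestError, ValueError):
    """A gain operation would push the peak beyond digital full scale."""


class StaircaseError(AuditestError, RuntimeError):
    """Invalid use of the adaptive track (e.g., update after finish)."""


class ManifestError(AuditestError, ValueError):
    """A stimulus manifest failed validation; message carries the row number."""


class SchemaVersionError(AuditestError, ValueError):
    """A results file was written with an incompatible schema version."""
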