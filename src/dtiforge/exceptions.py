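"""Exception hierarchy."""


class DtiforgeError(ValueError):
    """Base class for all package errors."""


class SequenceError(DtiforgeError):
    """Invalid protein sequence (nonstandard residue, too short, empty)."""


class StructureError(DtiforgeError):
    """Unparsable molecular structure; carries the offending record id."""

    def __init__(self, message: str, record_id: str | None = None):
        super().__init__(message)
        self.record_id = record_id


class CatalogError(DtiforgeError):
    """Inconsistent interaction catalog (unknown ids, duplicate pairs)."""


class SplitError(DtiforgeError):
    """A train/test split cannot be constructed as requested."""


class ConfigError(DtiforgeError):
    """Invalid run/profile/battery configuration."""
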