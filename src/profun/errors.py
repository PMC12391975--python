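"""Structured exceptions shared across the package."""


class ProfunError(Exception):
    """Base class for all package errors."""


class StructureParseError(ProfunError):
    """Raised when a structure file cannot be parsed into a residue chain."""


class EdgeListParseError(ProfunError):
    """Raised on malformed edge-list files."""


class OboParseError(ProfunError):
    """Raised on malformed or inconsistent OBO ontology files."""


class EmbeddingError(ProfunError):
    """Raised on missing or inconsistent embedding data."""


class ConfigError(ProfunError):
    """Raised on invalid configuration values."""
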