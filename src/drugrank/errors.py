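"""Exception hierarchy.

Every error raised on bad user input derives from :class:`DrugrankError`
so the CLI can map them to exit code 2 uniformly.
"""


class DrugrankError(Exception):
    """Base class for all drugrank errors."""


class MissingTableError(DrugrankError):
    """A required knowledge-base table file is absent."""


class IntegrityError(DrugrankError):
    """Referential integrity violated across knowledge-base tables."""


class SchemaError(DrugrankError):
    """A table cell does not conform to the documented schema."""


class FormatError(DrugrankError):
    """A patient input file (VCF/TSV/RNK) is malformed."""


class ConfigError(DrugrankError):
    """Scoring configuration is invalid (e.g. weights not summing to 1)."""


class EmptyQueryError(DrugrankError):
    """All patient input channels are empty."""
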