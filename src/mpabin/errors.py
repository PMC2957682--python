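"""Exception hierarchy shared across the package."""


class MpabinError(Exception):
    """Base class for all package-specific errors."""


class TaxonomyStructureError(MpabinError):
    """The taxonomy is structurally invalid (cycle, dangling parent, duplicate id, no/multiple roots)."""


class UnknownTaxidError(MpabinError, KeyError):
    """A tax_id was requested that is not present in the taxonomy."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class ParseError(MpabinError):
    """A tabular input row could not be parsed."""


class ConfigError(MpabinError):
    """A configuration file or object is invalid."""


class UsageError(MpabinError, ValueError):
    """An operation was called outside its contract (e.g. empty input list)."""


class DataError(MpabinError):
    """Inconsistent data across input files (e.g. read ids missing from the truth table)."""
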