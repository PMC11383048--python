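"""Exception types shared across the package."""


class SnpRecoverError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SnpRecoverError):
    """A required column is missing or a file header is malformed."""


class RowParseError(SnpRecoverError):
    """A cell in a data file could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class FormatError(SnpRecoverError):
    """A file does not conform to its documented text layout."""


class UnknownSnpError(SnpRecoverError):
    """snp_ids absent from a fixed vocabulary were encountered."""

    def __init__(self, snp_ids):
        self.snp_ids = sorted(set(snp_ids))
        shown = ", ".join(self.snp_ids[:10])
        more = "" if len(self.snp_ids) <= 10 else f" (+{len(self.snp_ids) - 10} more)"
        super().__init__(f"snp_ids not in vocabulary: {shown}{more}")


class UndefinedResultError(SnpRecoverError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
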