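"""Exception types shared across the package."""


class ParacoderError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ParacoderError):
    """A required resource (embedding lexicon, knowledge base, word list,
    threshold file) is missing, malformed, or inconsistent with the data —
    e.g. a test target that cannot be resolved in the embedding vocabulary."""


class MalformedTrialError(ParacoderError):
    """A trial row violates the input contract (missing field, unknown tag).

    Carries enough context to name the offending row.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
        self.row = row
        self.column = column
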