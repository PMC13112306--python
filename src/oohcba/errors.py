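"""Exception hierarchy for the oohcba pipeline."""


class OohcbaError(Exception):
    """Base class for all package errors."""


class ConfigError(OohcbaError):
    """Invalid configuration or generator settings."""


class BundleParseError(OohcbaError):
    """A CSV/JSON bundle file is missing, malformed, or violates an invariant."""

    def __init__(self, message: str, *, file: str | None = None,
                 column: str | None = None, row: int | None = None):
        loc = ", ".join(
            f"{k}={v}" for k, v in
            (("file", file), ("column", column), ("row", row)) if v is not None
        )
        super().__init__(f"{message}" + (f" [{loc}]" if loc else ""))
        self.file = file
        self.column = column
        self.row = row


class ModelError(OohcbaError):
    """The lifetable produced an inconsistent state (e.g. negative other-cause
    mortality, probability outside [0, 1])."""
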