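"""Exception types shared across the package."""


class EquiwagError(Exception):
    """Base class for package errors."""


class SchemaError(EquiwagError):
    """The question schema or an input file's structure is invalid."""


class ValidationError(EquiwagError):
    """One or more survey records violate the schema.

    Carries the individual problems in ``issues`` so callers can report
    every offending row, not just the first.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues[:20])
        more = "" if len(self.issues) <= 20 else f" (+{len(self.issues) - 20} more)"
        super().__init__(f"{len(self.issues)} validation issue(s): {lines}{more}")


class ConfigError(EquiwagError):
    """A run or generator configuration is invalid; names the field path."""

    def __init__(self, field_path: str, message: str):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")
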