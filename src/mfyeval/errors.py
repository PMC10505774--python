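"""Exceptions and warning categories used across the package."""


class MfyevalError(Exception):
    """Base class for package errors."""


class ValidationError(MfyevalError, ValueError):
    """An input value violates a documented precondition."""


class MissingColumnError(MfyevalError, KeyError):
    """A required column is absent from an input table."""

    def __init__(self, table: str, columns: list[str]):
        self.table = table
        self.columns = list(columns)
        super().__init__(f"table '{table}' is missing required column(s): {', '.join(columns)}")


class MissingDietError(MfyevalError, KeyError):
    """Cow records reference herds with no diet row."""

    def __init__(self, herd_ids: list):
        self.herd_ids = list(herd_ids)
        super().__init__(
            "no diet row for herd(s): " + ", ".join(str(h) for h in self.herd_ids)
        )


class DegenerateInputError(MfyevalError, ValueError):
    """A statistic is undefined for the given data (zero variance, n too small)."""


class EmptyInputError(MfyevalError, ValueError):
    """An input table contains no records."""


class PredictionWarning(UserWarning):
    """A prediction is outside its physically meaningful range (e.g. negative)."""
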