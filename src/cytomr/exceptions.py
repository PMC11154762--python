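"""Package-specific exceptions.

The selection pipeline distinguishes recoverable "signals" (empty selection,
too few surviving instruments) from genuine input errors; the orchestration
layer converts the former into a ``status`` field rather than aborting a run.
"""


class CytomrError(Exception):
    """Base class for all package errors."""


class SchemaError(CytomrError):
    """A required column is missing or unmappable in an input table."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"missing required column '{column}'{where}")


class EmptyInputError(CytomrError):
    """An input table produced zero valid records."""


class EmptySelectionError(CytomrError):
    """No SNP passed the exposure significance threshold.

    The caller may fall back to a looser threshold (the motivation for the
    secondary 5e-6 analysis when 5e-8 leaves too few instruments).
    """

    def __init__(self, threshold: float):
        self.threshold = threshold
        super().__init__(f"no SNP passed the exposure threshold p < {threshold:g}")


class InsufficientInstrumentsError(CytomrError):
    """Fewer instruments survive than an estimator or the pipeline requires."""

    def __init__(self, n_surviving: int, required: int):
        self.n_surviving = n_surviving
        self.required = required
        super().__init__(
            f"{n_surviving} instrument(s) available, {required} required"
        )


class DegenerateInstrumentError(CytomrError):
    """A Wald ratio was requested for a SNP with zero exposure effect."""
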