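"""Exception hierarchy shared by all analysis stages."""


class DnabindError(Exception):
    """Base class for all package errors."""


class ValidationError(DnabindError):
    """A domain-type invariant is violated."""


class LoadError(DnabindError):
    """A table could not be loaded; names the offending row/column where known."""

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        loc = []
        if column is not None:
            loc.append(f"column {column!r}")
        if row is not None:
            loc.append(f"row {row}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class ParameterError(DnabindError):
    """An operation was called with invalid parameters."""


class FitError(DnabindError):
    """A regression or nonlinear fit could not be performed."""


class NoTransitionError(FitError):
    """A melting curve shows no detectable helix-coil transition."""


class NoPeakError(DnabindError):
    """No voltammetric peak above the noise floor in the search window."""


class UsageError(DnabindError):
    """The pipeline configuration is unusable (e.g. no technique configured)."""
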