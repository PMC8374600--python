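"""Exception hierarchy shared by every module.

All domain failures derive from :class:`Recall24Error` so callers (and the
CLI) can distinguish engine errors from programming errors with one except
clause.
"""


class Recall24Error(Exception):
    """Base class for all engine errors."""


class ValidationError(Recall24Error):
    """An input value violates a documented precondition."""


class ParseError(Recall24Error):
    """A structured-text file does not conform to its schema.

    Carries ``line`` and ``field`` context where available.
    """

    def __init__(self, message: str, *, line: int | None = None, field: str | None = None):
        ctx = []
        if line is not None:
            ctx.append(f"line {line}")
        if field is not None:
            ctx.append(f"field {field!r}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.line = line
        self.field = field


class IntegrityError(Recall24Error):
    """A referential-integrity rule would be broken (dangling or duplicate id)."""


class StateError(Recall24Error):
    """An interview operation was attempted in a pass where it is not legal."""


class CompletenessError(Recall24Error):
    """Finalisation attempted while quick-list items remain undetailed."""

    def __init__(self, undetailed_labels: list[str]):
        self.undetailed_labels = list(undetailed_labels)
        super().__init__(
            "cannot finalise recall: undetailed items remain: "
            + ", ".join(repr(x) for x in self.undetailed_labels)
        )


class NoEquivalenceError(Recall24Error):
    """No gram weight is on file for the requested food/measure pair."""


class InsufficientDataError(Recall24Error):
    """Too few group members or shared measures for a statistical check."""
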