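"""Exception hierarchy.

Every user-facing failure derives from :class:`MeltingError` so the CLI can
map any engine failure to a one-line actionable message and a nonzero exit.
"""


class MeltingError(Exception):
    """Base class for all errors raised by this package."""


class SequenceParseError(MeltingError):
    """Strand text could not be tokenized; carries the failing offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class AlignmentError(MeltingError):
    """The two strands do not form a valid positional alignment."""


class ParameterLoadError(MeltingError):
    """An XML parameter file is malformed or violates the schema."""


class MissingParameterError(MeltingError, KeyError):
    """A thermodynamic lookup failed; carries the descriptor key."""

    def __init__(self, key, set_id: str | None = None):
        self.key = key
        self.set_id = set_id
        where = f" in parameter set '{set_id}'" if set_id else ""
        MeltingError.__init__(
            self,
            f"no thermodynamic entry for {key}{where}; supply a parameter "
            "set covering this pattern (option --nn or --data)",
        )

    def __str__(self) -> str:  # KeyError quotes its args otherwise
        return self.args[0]


class NoFormulaError(MeltingError):
    """No registered thermodynamic formula applies to a pattern."""


class TerminalMismatchError(NoFormulaError):
    """Mismatches must be internal; terminal mismatches are not computable."""


class NotApplicableError(MeltingError):
    """A forced formula or correction is outside its applicability scope."""


class UnknownMethodError(MeltingError):
    """A forced method/correction id is not registered."""


class ValidationError(MeltingError):
    """Invalid environment or degenerate numeric input."""
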