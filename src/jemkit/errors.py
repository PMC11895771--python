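"""Exception hierarchy for jemkit.

Every error raised by the library derives from :class:`JemError` so callers
(and the CLI) can distinguish data problems (exit 1) from configuration
problems (exit 2).
"""


class JemError(Exception):
    """Base class for all jemkit errors."""


class DomainError(JemError, ValueError):
    """An input value outside its mathematical domain (e.g. prevalence > 100)."""


class DataError(JemError, ValueError):
    """Structurally valid input whose content violates a contract."""


class LoadError(DataError):
    """A delimited file failed validation; carries row-numbered diagnostics."""

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = list(problems or [])
        if self.problems:
            message = message + "\n  " + "\n  ".join(self.problems)
        super().__init__(message)


class CodingSystemMismatch(DataError):
    """Two objects that must share an occupational coding system do not."""


class ConfigError(JemError, ValueError):
    """Invalid configuration (bad rule name, missing column mapping, ...)."""


class DegenerateStatisticError(JemError, ArithmeticError):
    """A statistic is undefined on this input (e.g. kappa with p_e = 1)."""
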