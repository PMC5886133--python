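"""Exception hierarchy for the financing-gaps toolkit."""


class FgapsError(Exception):
    """Base class for all package errors."""


class SchemaError(FgapsError):
    """A required column or field is missing or unresolvable."""


class PanelValidationError(FgapsError):
    """A country-year panel violates a structural invariant.

    Carries ``violations``, a list of human-readable strings that name the
    offending rows / keys, so callers can report every problem at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "panel validation failed:\n  " + "\n  ".join(self.violations)
        super().__init__(msg)


class ConfigError(FgapsError):
    """A run configuration value is out of bounds or inconsistent."""


class ModelError(FgapsError):
    """A statistical model cannot be fitted (rank deficiency, too few rows)."""


class AlignmentError(FgapsError):
    """Inputs that must share a key set (countries, years) do not."""
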