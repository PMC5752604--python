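"""Exception hierarchy for carecascade."""

from __future__ import annotations


class CascadeError(Exception):
    """Base class for all carecascade errors."""


class ValidationError(CascadeError):
    """A model or scenario file failed validation.

    Parameters
    ----------
    path:
        Dotted path of the offending field (e.g. ``sub_conditions[2].treated_cfr``).
    message:
        Human-readable description of the violation.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        self.message = message
        super().__init__(f"{path}: {message}" if path else message)


class SchemaVersionError(ValidationError):
    """The file declares a schema_version this library does not understand."""


class ConfigurationError(CascadeError):
    """An invalid runtime configuration (e.g. transfer probabilities > 1)."""


class CalibrationError(CascadeError):
    """An incidence calibration target is infeasible."""
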