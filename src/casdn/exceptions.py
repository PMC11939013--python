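"""Exception hierarchy shared by every pipeline stage.

Each class maps to one CLI exit code so shell callers can branch on the
failure class without parsing messages.
"""


class CasdnError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputOutputError(CasdnError):
    """Missing files, unreadable paths, unsupported containers."""

    exit_code = 2


class FormatError(InputOutputError):
    """A file exists but its pixel type or layout is unsupported."""


class ValidationError(CasdnError):
    """A parameter or array violates its documented contract."""

    exit_code = 3


class DimensionError(ValidationError):
    """Two arrays that must share a shape do not."""


class UndefinedMetricError(CasdnError):
    """A metric was requested on inputs where it has no defined value
    (e.g. Hausdorff distance of an empty boundary set)."""

    exit_code = 4
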