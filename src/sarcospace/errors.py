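"""Exception hierarchy.

``ValidationError`` covers malformed inputs (bad tables, unknown enum values,
axis mismatches); everything else raised by the package is a plain exception
or ``AnalysisError``. The CLI maps ValidationError to exit code 1 and other
failures to exit code 2.
"""


class SarcospaceError(Exception):
    """Base class for package errors."""


class ValidationError(SarcospaceError):
    """Malformed or inconsistent input data / configuration."""


class AnalysisError(SarcospaceError):
    """A computation could not be carried out on otherwise valid input."""
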