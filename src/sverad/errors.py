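"""Exception hierarchy.

All library errors derive from :class:`SveradError` so callers (and the CLI)
can distinguish bad input from genuine bugs.
"""


class SveradError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SveradError, ValueError):
    """A parameter or data value violates a documented precondition."""


class UniverseMismatchError(InvalidInputError):
    """Two vectors (or a vector and a model) disagree on the feature universe size."""


class CapacityError(SveradError):
    """An exhaustive enumeration was requested beyond the configured union-size guard."""


class UnsupportedModelError(SveradError):
    """A fitted model handle does not describe an RBF-kernel SVM on binary inputs."""


class ConfigurationError(SveradError):
    """A required optional component (e.g. Platt parameters) is missing."""
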