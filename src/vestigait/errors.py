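"""Exception hierarchy.

``VestigaitError`` is the base for everything the library raises on
purpose; the CLI maps :class:`ValidationError` subclasses to exit code 1
and any other failure to exit code 2.
"""


class VestigaitError(Exception):
    """Base class for all errors raised by vestigait."""


class ValidationError(VestigaitError, ValueError):
    """Invalid parameters or inconsistent inputs."""


class ParameterError(ValidationError):
    """A scalar parameter is out of its documented range."""


class AliasingError(ValidationError):
    """Sampling rate too low for the requested bandwidth."""


class LengthError(ValidationError):
    """A signal is too short for the requested operation."""


class InsufficientDataError(ValidationError):
    """Fewer gait events / strides than the analysis requires."""


class NoContactError(ValidationError):
    """Vertical force never exceeds the contact floor."""
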