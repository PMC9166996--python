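"""Exception hierarchy shared by all ctdenoise modules."""


class CTDenoiseError(Exception):
    """Base class for all errors raised by ctdenoise."""


class ParameterError(CTDenoiseError, ValueError):
    """A parameter is outside its documented domain."""


class DimensionError(CTDenoiseError, ValueError):
    """Array shapes are inconsistent or too small for the operation."""


class FormatError(CTDenoiseError, IOError):
    """An image file is in an unsupported or unreadable format."""


class ChannelError(CTDenoiseError, ValueError):
    """A multi-channel image was supplied where grayscale is required."""


class EmptyInputError(CTDenoiseError, ValueError):
    """An operation that needs data received an empty collection."""


class UndefinedMetricError(CTDenoiseError, ZeroDivisionError):
    """A ratio metric was requested with a zero denominator."""
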