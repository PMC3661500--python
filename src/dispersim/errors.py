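"""Exception hierarchy shared across the simulator."""


class DispersimError(Exception):
    """Base class for all simulator errors."""


class ConfigurationError(DispersimError):
    """A run configuration or input file is missing something required."""


class MapValidationError(DispersimError):
    """A parameter-map attribute is outside its legal range, or the map has gaps."""


class FormatError(DispersimError):
    """An input file is not in the expected vector format."""


class GeometryError(DispersimError):
    """A supplied geometry is invalid."""


class OutOfBoundsError(DispersimError):
    """A query point lies outside the landscape extent."""


class InvalidStateError(DispersimError):
    """The simulation reached a state the model forbids (e.g. an animal inside
    an impassable movement class)."""


class SchedulingError(DispersimError):
    """An operation was applied out of temporal order."""
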