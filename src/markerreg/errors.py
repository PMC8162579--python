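"""Exception types shared across the toolkit."""


class MarkerRegError(Exception):
    """Base class for all toolkit errors."""


class ModelParseError(MarkerRegError, ValueError):
    """A model or definitions file could not be parsed."""


class ModelValidationError(MarkerRegError, ValueError):
    """A structural invariant of the kinematic model is violated."""


class FileFormatError(MarkerRegError, ValueError):
    """A TRC/MOT/STO file is malformed."""


class DegenerateFrameError(MarkerRegError, ValueError):
    """Anatomical frame construction received near-parallel directions."""


class UnderdeterminedError(MarkerRegError, ValueError):
    """Too few usable marker targets to determine a pose."""
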