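"""Exception hierarchy for camnoise."""


class CamnoiseError(Exception):
    """Base class for all camnoise errors."""


class UnknownBufferError(KeyError, CamnoiseError):
    """Requested buffer name is not in the shipped kinetics table."""


class UnsupportedSystemError(CamnoiseError):
    """Operation requires a different system class (e.g. single-buffer only)."""


class CapacityError(CamnoiseError):
    """State space too large for an exact enumeration."""


class EstimationError(CamnoiseError):
    """A statistical estimator could not produce a usable value."""


class DegenerateInputError(CamnoiseError):
    """Input is degenerate for the requested statistic (e.g. constant series)."""
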