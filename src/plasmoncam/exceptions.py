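"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors exit 2, data/format errors
exit 3, numerical failures exit 4.
"""


class PlasmonCamError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PlasmonCamError):
    """Invalid configuration: unknown keys, bad geometry, unknown material."""


class FormatError(PlasmonCamError):
    """Malformed data: wrong channel count, band mismatch, missing columns."""


class RangeError(PlasmonCamError):
    """A quantity outside its supported domain (e.g. band outside the grid)."""


class StateError(PlasmonCamError):
    """Operation called on an object in the wrong state (e.g. unfitted scaler)."""


class NumericalError(PlasmonCamError):
    """Numerical failure, e.g. divergence of network training."""
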