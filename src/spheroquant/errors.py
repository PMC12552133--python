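"""Exception hierarchy for spheroquant.

All pipeline stages raise subclasses of :class:`SpheroQuantError` so that
callers (and the CLI) can distinguish analysis failures from programming
errors.
"""


class SpheroQuantError(Exception):
    """Base class for all spheroquant errors."""


class ConfigError(SpheroQuantError):
    """Invalid configuration or parameter value."""


class ChannelError(SpheroQuantError):
    """Unknown channel name or channel-map mismatch."""


class FieldError(SpheroQuantError):
    """Requested field of view cannot contain the phantom."""


class SegmentationError(SpheroQuantError):
    """Spheroid segmentation failed or is unreliable."""


class ProfileError(SpheroQuantError):
    """Radial profiling failed (no nuclei, degenerate sectors, ...)."""


class PenetrationError(SpheroQuantError):
    """Penetration estimation received invalid input."""


class PlateError(SpheroQuantError):
    """Plate-table analysis failed (degenerate controls, too few doses, ...)."""


class ReadError(SpheroQuantError):
    """Image file could not be read or validated."""
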