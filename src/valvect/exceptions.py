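"""Exception hierarchy.

The CLI maps these onto exit codes: input/format problems -> 2,
calibration problems -> 3, geometry problems -> 4.
"""


class ValvectError(Exception):
    """Base class for all package errors."""


class InputError(ValvectError):
    """Missing or malformed input file (NIfTI volume, plane sidecar, config)."""


class PlaneValidationError(InputError):
    """Valve-plane definition violates its geometric contract."""


class CalibrationError(ValvectError):
    """Blood-pool statistics cannot yield a usable threshold set."""


class GeometryError(ValvectError):
    """Reslicing or annulus geometry failure (e.g. stack exits the volume)."""


class SegmentationError(ValvectError):
    """Invalid seed or ROI passed to region growing."""


class CapacityError(ValvectError):
    """Requested phantom tissue volumes exceed the geometric capacity."""


class StatsError(ValvectError):
    """Degenerate input to a statistical routine."""
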