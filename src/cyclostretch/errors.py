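"""Exception hierarchy shared across the package."""


class CycloStretchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CycloStretchError, ValueError):
    """Invalid protocol, parameter set, preset name or schedule."""


class DimensionError(CycloStretchError, ValueError):
    """Geometry does not fit the requested canvas."""


class DynamicsError(CycloStretchError, RuntimeError):
    """A simulated cycle could not be realized (e.g. retraction would empty the cell)."""


class InputError(CycloStretchError, ValueError):
    """Invalid measurement input (empty mask, shape mismatch, bad lengths)."""


class DetectionError(CycloStretchError, RuntimeError):
    """Fiducial-grid detection failed or found too few squares."""


class PairingError(CycloStretchError, ValueError):
    """Reference and deformed grid fits cannot be paired."""


class ScheduleError(CycloStretchError, ValueError):
    """A frame required by the acquisition schedule is missing."""


class AlignmentError(CycloStretchError, ValueError):
    """Condition tables do not share common timepoints."""
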