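"""Exception hierarchy for the asoct toolkit."""


class AsoctError(Exception):
    """Base class for all toolkit errors."""


class DomainError(AsoctError, ValueError):
    """A parameter is outside its physical domain (e.g. reflectivity > 1)."""


class OrderingError(AsoctError, ValueError):
    """Anterior-segment interfaces are not in strictly increasing axial order."""


class GeometryError(AsoctError, ValueError):
    """A geometric construction is inconsistent (e.g. surfaces would cross)."""


class OpticsError(AsoctError, ValueError):
    """An optical configuration is unrealizable (e.g. no real diffraction angle)."""


class MisuseError(AsoctError, ValueError):
    """An operation was applied to an object it is not meant for."""


class RegistrationError(AsoctError, RuntimeError):
    """Frame registration failed (insufficient correlation between frames)."""


class DetectionError(AsoctError, RuntimeError):
    """No qualifying peak was found in an A-scan."""


class IncompleteSegmentationError(AsoctError, RuntimeError):
    """Fewer principal boundary peaks were found than the anatomy requires."""

    def __init__(self, found, message=None):
        self.found = list(found)
        super().__init__(message or f"incomplete segmentation; found peaks: {self.found}")


class TracingError(AsoctError, RuntimeError):
    """A boundary could not be traced over enough of its aperture."""

    def __init__(self, surface, coverage=None):
        self.surface = surface
        self.coverage = coverage
        msg = f"boundary tracing failed for {surface!r}"
        if coverage is not None:
            msg += f" (coverage {coverage:.0%})"
        super().__init__(msg)


class FitError(AsoctError, RuntimeError):
    """A nonlinear fit failed to converge from every starting point."""
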