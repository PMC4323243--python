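"""Exception and warning types shared across the package."""


class CephaloplaneError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(CephaloplaneError):
    """Raised when a geometric construction is ill-posed.

    Examples: three (near-)collinear points offered as a plane, a
    basion-nasion axis parallel to the horizontal plane normal, or a
    rigid superimposition attempted on fewer than three non-collinear
    correspondences.
    """


class MissingLandmarkError(CephaloplaneError, KeyError):
    """A required landmark is absent from a landmark set."""

    def __init__(self, names):
        if isinstance(names, str):
            names = [names]
        self.names = list(names)
        super().__init__(f"missing landmark(s): {', '.join(self.names)}")

    def __str__(self):  # KeyError would repr() the message otherwise
        return f"missing landmark(s): {', '.join(self.names)}"


class ParseError(CephaloplaneError, ValueError):
    """A landmark file could not be parsed; carries the offending row."""

    def __init__(self, message, row=None, path=None):
        self.row = row
        self.path = path
        where = []
        if path is not None:
            where.append(str(path))
        if row is not None:
            where.append(f"row {row}")
        prefix = f"[{' '.join(where)}] " if where else ""
        super().__init__(prefix + message)


class PairingError(CephaloplaneError):
    """Repeated-measurement trials could not be paired for reliability."""


class UsageError(CephaloplaneError, ValueError):
    """Invalid arguments for an otherwise well-formed request."""


class TopologyError(CephaloplaneError):
    """A surface mesh is not a closed 2-manifold where one is required."""


class UndefinedRatioError(CephaloplaneError, ZeroDivisionError):
    """Soft-to-hard ratio requested with (near-)zero hard-tissue movement."""


class EmptyRegionWarning(UserWarning):
    """A region clip produced an empty volume."""
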