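"""Exception hierarchy.

Each error class maps to a distinct CLI exit code (see cli.EXIT_CODES).
"""


class MprError(Exception):
    """Base class for all mprkit errors."""


class NoDicomInputError(MprError):
    """A directory contained no readable DICOM files."""


class InconsistentSeriesError(MprError):
    """Slices within one series disagree on matrix dimensions."""


class UnsupportedDicomError(MprError):
    """Compressed transfer syntax or multi-frame object."""


class InsufficientSeriesError(MprError):
    """Fewer than two slices: no inter-slice geometry to work with."""


class MixedOrientationError(MprError):
    """Slice normals within one series disagree."""


class GeometryError(MprError):
    """Degenerate orientation cosines or broken ordering invariant."""


class EmptySeriesError(MprError):
    """Zero input files where the reconstruction protocol requires >= 1."""


class ParameterError(MprError):
    """Invalid user-supplied parameter (window width, z step request, ...)."""


class BoundsError(MprError):
    """Index or point outside the image/volume extent."""


class EmptyRoiError(MprError):
    """ROI does not cover any pixel center."""


class NoEdgesError(MprError):
    """Intensity profile is flat; no half-maximum crossing exists."""


class StructureNotFoundError(MprError):
    """Fewer than two edges on a profile; extent undefined."""


class NoDiscreteExtentsError(MprError):
    """Phantom insert (e.g. gradient) has no discrete physical extents."""
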