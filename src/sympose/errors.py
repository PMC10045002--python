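"""Exception hierarchy for sympose."""


class SymposeError(Exception):
    """Base class for all sympose errors."""


class UnreadableVolumeError(SymposeError):
    """Volume file missing, malformed, or with invalid metadata."""


class UnreadableMeshError(SymposeError):
    """Mesh file missing, truncated, or containing no usable facets."""


class EmptyVolumeError(SymposeError):
    """An analysis entry point received a volume with no occupied voxel."""


class NotRigidError(SymposeError, ValueError):
    """A 4x4 matrix is not a proper rigid transform."""


class PhantomFitError(SymposeError):
    """The parametric phantom solid does not fit the requested grid."""


class DegenerateContourError(SymposeError):
    """Rasterized point set collapses to fewer than three cells."""


class OpenContourError(SymposeError):
    """Area operations require a closed contour."""


class ContourTooShortError(SymposeError):
    """Contour has too few points for the requested bending half-width."""


class NoTurningPointsError(SymposeError):
    """No contour point passed the turning-point criteria."""


class DegenerateFrameError(SymposeError):
    """Third principal axis (nearly) parallel to the symmetry-plane normal."""


class DegenerateAnchorsError(SymposeError):
    """Anchor points coincide; the local frame is undefined."""


class CollinearAnchorsError(SymposeError):
    """P1, P2, P3 are collinear; no frame can be built."""


class DegenerateCorrespondenceError(SymposeError):
    """All matched points coincide; no rigid fit exists."""


class ConfigError(SymposeError, ValueError):
    """Invalid or unknown pipeline configuration."""
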