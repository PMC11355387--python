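"""Exception hierarchy. All derive from ValueError so callers can be coarse."""


class CactusCoverError(ValueError):
    """Base class for package errors."""


class InvalidParameterError(CactusCoverError):
    """A parameter violates its documented domain."""


class AlignmentError(CactusCoverError):
    """Image/mask (or mask/mask) shapes do not line up."""


class ReassemblyError(CactusCoverError):
    """Tiles cannot be stitched back into a parent raster."""


class ConfigurationError(CactusCoverError):
    """A run configuration is inconsistent or infeasible."""


class ShapeError(CactusCoverError):
    """An array has the wrong shape for a model or operation."""
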