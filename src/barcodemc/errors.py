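"""Exception hierarchy shared across the package."""


class BarcodeMCError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BarcodeMCError, ValueError):
    """A physical parameter is outside its admissible range."""


class BandRangeError(BarcodeMCError, ValueError):
    """A wavelength query falls outside the tabulated band (no extrapolation)."""


class GeometryError(BarcodeMCError, ValueError):
    """A geometric element does not fit in, or protrudes from, the domain."""


class DiscretizationError(GeometryError):
    """A length is not an integer multiple of the voxel size."""


class AlignmentError(BarcodeMCError, ValueError):
    """Two spectra do not share the same wavelength-bin plan."""


class DegenerateSourceError(BarcodeMCError, RuntimeError):
    """An emission source distribution has zero total weight."""


class ConfigError(BarcodeMCError, ValueError):
    """A run configuration failed validation."""
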