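"""Exception hierarchy shared across the package."""


class RiboflexError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RiboflexError):
    """A structure file could not be parsed; the message names the offending line."""


class EmptyStructureError(RiboflexError):
    """A parsed file contained no polymer (protein or RNA) chains."""


class EmptySelectionError(RiboflexError):
    """A chain/atom selection matched nothing (e.g. no C-alpha atoms)."""


class ChainClassError(RiboflexError):
    """An operation received a chain of the wrong polymer class."""


class ParameterError(RiboflexError):
    """An argument is outside its valid domain (non-positive cutoff, C >= N, ...)."""


class SpectralSanityError(RiboflexError):
    """The rigid-mode count of a mode spectrum disagrees with the expected value."""


class DegenerateSpectrumError(RiboflexError):
    """All modes of a spectrum are rigid; no fluctuations can be computed."""


class TipFilterError(RiboflexError):
    """The automatic tip-outlier rule would remove too many residues; manual review needed."""


class GenerationError(RiboflexError):
    """A synthetic fixture could not be realized under its geometric constraints."""


class AlignmentError(RiboflexError):
    """Coordinate sets or sequences cannot be brought into correspondence."""


class MappingError(RiboflexError):
    """A residue identifier does not map into the sequence/alignment it refers to."""


class ConfigurationError(RiboflexError):
    """A pipeline run configuration is invalid or references missing chains/files."""
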