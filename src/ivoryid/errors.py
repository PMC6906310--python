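"""Exception hierarchy for ivoryid."""


class IvoryIdError(Exception):
    """Base class for all ivoryid errors."""


class CoordinateError(IvoryIdError, ValueError):
    """A position falls outside the 116 bp fragment coordinate frame."""


class PanelIntegrityError(IvoryIdError):
    """The reference panel is internally inconsistent."""


class ValidationError(IvoryIdError, ValueError):
    """Invalid input to a sequence operation."""


class FastaParseError(IvoryIdError, ValueError):
    """A FASTA file could not be parsed or contains illegal characters."""


class AlignmentError(IvoryIdError, ValueError):
    """Sequences are not comparable position-by-position."""


class UndefinedDistanceError(IvoryIdError, ArithmeticError):
    """A pairwise distance is undefined (no comparable sites)."""


class SaturationError(IvoryIdError, ArithmeticError):
    """Divergence too large for the distance correction (log argument <= 0)."""


class InsufficientDataError(IvoryIdError, ValueError):
    """Too few sequences for the requested summary."""


class GapUndefinedError(IvoryIdError, ValueError):
    """Barcoding gap requires at least one intra- and one inter-class pair."""


class ConfigurationError(IvoryIdError, ValueError):
    """Invalid run configuration."""
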