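"""Exception hierarchy shared by all acr3kit modules."""


class Acr3KitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Acr3KitError):
    """A file does not conform to the expected format (FASTA, PDB, ...)."""


class StructureError(Acr3KitError):
    """A structure model violates a structural requirement (e.g. missing CA)."""


class InputError(Acr3KitError):
    """Invalid input data passed to an operation."""


class ParameterError(Acr3KitError):
    """Invalid parameter value or missing force-field parameter."""


class SaturationError(Acr3KitError):
    """Substitution proportion too high for the distance correction to apply."""


class DegenerateInputError(Acr3KitError):
    """Input is degenerate for the requested statistic (e.g. zero synonymous sites)."""


class DimensionError(Acr3KitError):
    """Requested embedding dimension exceeds the usable rank."""

    def __init__(self, message: str, usable_rank: int | None = None):
        super().__init__(message)
        self.usable_rank = usable_rank


class ComparisonError(Acr3KitError):
    """Two objects are not comparable (e.g. contact maps with different cutoffs)."""


class ClashError(Acr3KitError):
    """Atoms closer than the hard-core limit for the energy model."""


class ConfigError(Acr3KitError):
    """Invalid or incomplete analysis configuration."""
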