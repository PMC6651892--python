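"""Exception hierarchy used across the package."""


class ZooChimeraError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(ZooChimeraError):
    """Feature vectors of inconsistent or mismatched dimensionality."""


class IntegrityError(ZooChimeraError):
    """Structural inconsistency: duplicate keys, missing references, bad caps."""


class EmptyInputError(ZooChimeraError):
    """An operation received an empty table or an empty population."""


class InsufficientSamplesError(ZooChimeraError):
    """An individual has too few samples for the requested statistic."""


class InsufficientPopulationError(ZooChimeraError):
    """Too few individuals for a between-individual statistic."""


class ConstraintViolationError(ZooChimeraError):
    """A menagerie combination constraint cannot be satisfied (e.g. sheep
    are not the majority after goat/lamb selection)."""


class DegenerateNormalizationError(ZooChimeraError):
    """Min-max normalization requested on a constant score collection."""


class UndefinedCorrelationError(ZooChimeraError):
    """Spearman distance on a vector with zero rank variance."""


class UndefinedDecidabilityError(ZooChimeraError):
    """Decidability is 0/0: both score classes constant and equal."""


class ValidationError(ZooChimeraError):
    """Invalid configuration values."""
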