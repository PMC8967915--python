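"""Exception hierarchy for the QC toolkit.

Every error raised by the package derives from :class:`ScqcError` so callers
can catch toolkit failures without masking programming errors.
"""


class ScqcError(Exception):
    """Base class for all toolkit errors."""


class DimensionError(ScqcError):
    """A vector or matrix does not match the experiment's dimensions."""


class NameCollisionError(ScqcError):
    """An annotation column with this name already exists."""


class LevelTransitionError(ScqcError):
    """Requested matrix-level transition is not allowed.

    Levels only move forward by column subsetting: Droplet -> Cell ->
    FilteredCell (or stay in place).
    """


class IncompatibleFeaturesError(ScqcError):
    """Experiments to be combined do not share an identical gene universe."""


class FormatError(ScqcError):
    """An input file violates its declared on-disk format."""


class LayoutError(ScqcError):
    """An expected file or directory is missing from a tool's output layout."""


class DuplicateFeatureError(FormatError):
    """Input contains duplicate gene identifiers."""


class InsufficientDataError(ScqcError):
    """Not enough barcodes/cells to run the requested computation."""


class AmbientPoolError(ScqcError):
    """No low-count barcodes available to build an ambient profile."""


class ParameterError(ScqcError):
    """A parameter value is outside its valid range."""


class MissingResultError(ScqcError):
    """A downstream step requires results that have not been computed."""


class MissingColumnError(ScqcError):
    """A named cell-annotation column does not exist."""


class DegenerateInputError(ScqcError):
    """Input has no usable variation for the requested algorithm."""


class CannotEstimateError(ScqcError):
    """The model is unidentifiable on this input (e.g. a single cluster)."""


class ConfigError(ScqcError):
    """Pipeline configuration is invalid."""
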