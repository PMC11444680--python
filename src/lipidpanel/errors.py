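"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`LipidPanelError`, so callers
can catch package failures without swallowing programming errors.
"""


class LipidPanelError(Exception):
    """Base class for all lipidpanel errors."""


class FormatError(LipidPanelError):
    """A table cell or file layout could not be parsed."""


class JoinError(LipidPanelError):
    """Sample ids of the values table and the metadata table do not match."""


class ConsistencyError(LipidPanelError):
    """Dataset invariants violated (duplicate ids, impossible metadata)."""


class DegenerateTaskError(LipidPanelError):
    """A classification task has fewer than two classes."""


class ParameterError(LipidPanelError):
    """An operation received an invalid parameter or specification."""


class SampleSizeError(LipidPanelError):
    """Too few observations for a statistic to be defined."""


class DomainError(LipidPanelError):
    """Input values outside the mathematical domain of an operation."""


class ConstantFeatureError(LipidPanelError):
    """A feature with zero variance where positive spread is required."""


class EmptyDatasetError(LipidPanelError):
    """Filtering removed everything."""


class ImputationError(LipidPanelError):
    """Preconditions of the iterative imputer are not met."""


class ClusteringFailure(LipidPanelError):
    """The U-matrix height field offers no ridge to split on."""


class DegenerateTableError(LipidPanelError):
    """A contingency table with an empty margin."""


class SplitError(LipidPanelError):
    """Holdout segregation impossible (a class has too few subjects)."""


class MetricError(LipidPanelError):
    """A performance metric is undefined for the given labels."""


class SchemaError(LipidPanelError):
    """An external dataset misses required features."""


class PipelineError(LipidPanelError):
    """A pipeline stage failed; carries stage context."""
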