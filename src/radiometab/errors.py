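"""Exception hierarchy shared across the pipeline.

Every failure mode the table readers, QC filters, fitters, and endpoint
analyses can hit maps to one of these classes, so callers (and the CLI)
can distinguish bad input data from bad configuration.
"""


class RadiometabError(Exception):
    """Base class for all package errors."""


class SchemaError(RadiometabError):
    """A table does not match its declared schema (missing column, empty file)."""


class IntegrityError(RadiometabError):
    """Duplicate primary-key tuples or inconsistent keys within a table."""


class ParseError(RadiometabError):
    """A cell failed numeric parsing; message carries the row index."""


class ValidationError(RadiometabError):
    """A value violates a domain invariant (negative area, p outside [0,1], ...)."""


class ConfigurationError(RadiometabError):
    """Invalid RunConfig values or missing configuration (e.g. replicate labels)."""


class PairingError(RadiometabError):
    """A cell line lacks the matched condition needed for a paired computation."""


class SampleSizeError(RadiometabError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(RadiometabError):
    """Zero-variance or otherwise degenerate input to a statistic."""


class AssayError(RadiometabError):
    """A clonogenic assay is unusable (e.g. plating efficiency of zero)."""


class FitError(RadiometabError):
    """A model fit is underdetermined or failed to converge."""


class NotReachedError(RadiometabError):
    """A threshold crossing (GI50, median) is not reached within the data range."""


class NormalizationError(RadiometabError):
    """A sample normalization factor is zero, negative, or undefined."""


class GroupingError(RadiometabError):
    """A required group label is absent from an event table."""


class EmptyPanelError(RadiometabError):
    """All metabolites were removed by filtering."""


class PipelineError(RadiometabError):
    """A pipeline stage failed; message names the stage and the cause."""
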