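"""Typed error hierarchy.

Every validation failure in the pipeline raises exactly one of these, so
callers (and tests) can distinguish malformed files from statistical
degeneracies without string matching.
"""


class ModulearnError(Exception):
    """Base class for all package errors."""


class FormatError(ModulearnError):
    """A file does not conform to the expected tabular layout (missing or
    unknown columns, bad header)."""


class ParseError(ModulearnError):
    """A cell could not be parsed; the message names the row and column."""


class DataValidationError(ModulearnError):
    """Structurally well-formed data that violates a study-design invariant
    (e.g. an episode label inconsistent with the cohort schedule)."""


class ParameterError(ModulearnError):
    """An invalid parameter value (non-PSD correlation, rate outside [0,1), ...)."""


class DegenerateInputError(ModulearnError):
    """Input that makes the requested fit meaningless (single-class labels,
    too few observations per class)."""


class ContractError(ModulearnError):
    """A call that violates an interface contract (predicting with missing or
    unknown variables, profiling an empty selection)."""


class UndefinedMetricError(ModulearnError):
    """A metric that is undefined for the given input (balanced accuracy with
    a single-class truth vector)."""


class UndefinedEffectError(ModulearnError):
    """An effect size that is undefined (zero pooled standard deviation)."""


class InsufficientDataError(ModulearnError):
    """Too few episodes to run the requested analysis."""


class ConfigurationError(ModulearnError):
    """An analysis configuration that cannot be satisfied by the data
    (e.g. more folds than minority-class participant groups)."""


class UnsupportedOperationError(ModulearnError):
    """Operation not available for this classifier family."""


class DegenerateSampleWarning(UserWarning):
    """All paired differences are zero; the signed-rank test is vacuous."""


class SeparationWarning(UserWarning):
    """Perfect separation detected; a lightly ridge-penalized fit was used."""
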