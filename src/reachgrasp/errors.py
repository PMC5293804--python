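"""Exception hierarchy for the reachgrasp pipeline.

All pipeline stages raise subclasses of :class:`ReachGraspError` so the CLI can
report the failing stage. Per-trial segmentation problems are *not* exceptions:
they are carried as flags on the trial record so a single bad trial never aborts
an experiment-level run.
"""


class ReachGraspError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ReachGraspError, ValueError):
    """A numeric argument is non-finite or outside its documented domain."""


class ConfigurationError(ReachGraspError, ValueError):
    """A configuration object violates one of its invariants."""


class SchemaError(ReachGraspError):
    """A table is missing a required column or has the wrong layout."""


class DataError(ReachGraspError):
    """A table's values violate a structural invariant (e.g. non-monotone time)."""


class VocabularyError(ReachGraspError):
    """A categorical token is outside its enumerated domain."""


class InsufficientDataError(ReachGraspError):
    """Too few subjects/observations for the requested inference."""


class EmptyAnalysisError(ReachGraspError):
    """Every subject was excluded; nothing left to analyze."""


class NumericalFailureError(ReachGraspError):
    """A numerical routine produced a non-finite result."""
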