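"""Exception hierarchy for refstab.

All errors raised on bad user input derive from :class:`RefstabError` so
callers (and the CLI) can distinguish validation problems (exit code 2)
from insufficient-data problems (exit code 3).
"""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class SchemaError(RefstabError):
    """An input table is missing a required column or has a malformed field."""


class ValidationError(RefstabError):
    """A value violates an invariant (e.g. non-positive included intensity)."""


class DuplicateRecordError(ValidationError):
    """More than one record for the same (animal, candidate) pair."""


class DomainError(ValidationError):
    """A value outside its documented domain (e.g. experiment not in 1..10)."""


class UnknownCandidateError(RefstabError):
    """A candidate id absent from the dataset was requested."""


class InsufficientDataError(RefstabError):
    """Too few animals, groups or candidates for the requested statistic."""


class IncompleteDesignError(RefstabError):
    """A combination-score table does not cover all required subsets."""
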