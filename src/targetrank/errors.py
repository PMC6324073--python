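"""Exception hierarchy.

Every contract violation raised by this package derives from
:class:`TargetRankError`, so callers (including the CLI) can catch one type
and turn it into a one-line diagnostic.
"""


class TargetRankError(Exception):
    """Base class for all targetrank domain errors."""


class EvidenceParseError(TargetRankError):
    """A JSON Lines record could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class RegistryError(TargetRankError):
    """A data source is absent from the registry or its type is inconsistent."""


class EvidenceValidationError(TargetRankError):
    """An evidence record failed field-level validation."""


class ScoringDomainError(TargetRankError):
    """A scoring-rule input lies outside its mathematical domain."""


class RuleMismatchError(TargetRankError):
    """An evidence record was passed to a scoring rule for a different source."""


class UnknownTermError(TargetRankError):
    """A clinical-significance term has no configured score."""


class UnscorableEvidenceError(TargetRankError):
    """No scoring rule applies and no precomputed score is present."""


class GraphLookupError(TargetRankError):
    """An entity is not a vertex of the bipartite graph."""


class BatchSizeError(TargetRankError):
    """A batch query exceeds the 200-identifier limit."""


class EmptyQueryError(TargetRankError):
    """No identifier in a batch query resolved against the universe."""


class PlantingError(TargetRankError):
    """A requested planted association score is unreachable."""


class FixtureConfigError(TargetRankError):
    """A synthetic-fixture configuration is internally inconsistent."""
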