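"""Exception hierarchy for zoosem.

All package-specific errors derive from :class:`ZooSemError` so callers can
catch one base class; subclasses also inherit from the closest built-in
(``KeyError``/``ValueError``) so generic handling keeps working.
"""


class ZooSemError(Exception):
    """Base class for all zoosem errors."""


class UnknownInstitutionError(ZooSemError, KeyError):
    """An institution id was not found in the holdings table."""


class DegenerateInputError(ZooSemError, ValueError):
    """Input is structurally valid but degenerate for the requested operation
    (empty collection, single-institution dissimilarity, constant column...)."""


class VocabularyError(ZooSemError, ValueError):
    """A categorical code falls outside its closed vocabulary."""


class UnresolvedMassError(ZooSemError, ValueError):
    """A species body mass could not be resolved at any taxonomic level."""


class SpecificationError(ZooSemError, ValueError):
    """A path-model specification is invalid (cycle, duplicate or missing edge)."""


class ParseError(SpecificationError):
    """A model-specification text could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DataError(ZooSemError, ValueError):
    """The dataset cannot support estimation (singular covariance, too few rows)."""


class ConvergenceError(ZooSemError, RuntimeError):
    """The maximum-likelihood optimiser failed to converge."""


class ConfigError(ZooSemError, ValueError):
    """A simulation or analysis configuration is infeasible."""
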