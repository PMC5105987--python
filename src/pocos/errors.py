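"""Exception hierarchy for the pocos package."""


class PocosError(Exception):
    """Base class for all pocos errors."""


class ParseError(PocosError):
    """A genotype or annotation file could not be parsed.

    Carries the offending file and (1-based) line number where known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ConsistencyError(PocosError):
    """Companion files disagree (sample/locus counts, truncated records)."""


class ValidationError(PocosError):
    """Well-formed input violating a dataset invariant (alleles, phenotype)."""


class UndefinedTestError(PocosError):
    """A statistical test is undefined for the given data (e.g. empty class)."""


class AlignmentError(PocosError):
    """Feature columns of a prediction input do not match the fitted model."""


class ConvergenceError(PocosError):
    """An iterative fit failed to converge within its iteration cap."""


class EmptyNetworkError(PocosError):
    """The heterogeneous network contains no usable locus nodes."""


class SimulationError(PocosError):
    """A simulation specification is infeasible."""
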