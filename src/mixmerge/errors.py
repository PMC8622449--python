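"""Exception hierarchy for mixmerge."""


class MixMergeError(Exception):
    """Base class for all mixmerge errors."""


class DomainError(MixMergeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateWeightsError(MixMergeError, ValueError):
    """Point weights sum to zero."""


class DegeneratePairError(MixMergeError, ValueError):
    """A component pair has zero effective mass, so the pair criterion is undefined."""


class DegenerateClusterError(MixMergeError, ValueError):
    """A merged cluster carries zero posterior mass."""


class UndefinedNMCError(MixMergeError, ValueError):
    """NMC is undefined because its entropy denominator is zero."""


class NumericalUnderflowError(MixMergeError, ArithmeticError):
    """All component densities underflowed at some data point."""
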