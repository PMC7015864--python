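"""Exception hierarchy for hetlncsim."""


class HetLncSimError(Exception):
    """Base class for all package errors."""


class FormatError(HetLncSimError):
    """Malformed input file (wrong column count, non-numeric cell, ...)."""


class CycleError(HetLncSimError):
    """The disease hierarchy contains a directed cycle."""


class UndefinedSimilarityError(HetLncSimError):
    """A pairwise score is mathematically undefined (zero-norm vector,
    constant expression profile); callers skip the pair and log it."""


class CoverageError(HetLncSimError):
    """An lncRNA cannot be scored by a layer (no usable partners)."""


class SamplingError(HetLncSimError):
    """Requested more negative pairs than are available."""
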