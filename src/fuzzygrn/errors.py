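"""Exception hierarchy for fuzzygrn.

Every rejected input surfaces as a named subclass of :class:`FuzzyNetworkError`
so callers (and the CLI) can distinguish bad data from bad configuration.
"""


class FuzzyNetworkError(Exception):
    """Base class for all fuzzygrn errors."""


class DataValidationError(FuzzyNetworkError):
    """Malformed or out-of-contract input data (non-finite cells, bad shapes,
    zero-variance observations, misaligned series)."""


class DomainError(FuzzyNetworkError):
    """A value outside the mathematical domain of an operation, e.g. a
    normalized expression value outside [-1, 1] or a tangent-pole input."""


class DegenerateTripleError(FuzzyNetworkError):
    """Defuzzification of an all-zero fuzzy triple: the centroid is undefined,
    which indicates an empty or degenerate model rather than a data problem."""


class SearchSpaceError(FuzzyNetworkError):
    """The exhaustive search would exceed the configured model-count cap."""


class NetworkAssemblyError(FuzzyNetworkError):
    """Node models cannot be consolidated into a composite network
    (duplicate outputs, unresolvable inputs, missing phenotype model)."""


class SimulationError(FuzzyNetworkError):
    """Invalid simulation request (incomplete initial state, clamping the
    phenotype node, no trajectory converged in a viability screen)."""
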