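"""Exception hierarchy for grnbench."""


class GrnBenchError(Exception):
    """Base class for all grnbench errors."""


class InvalidConfigError(GrnBenchError):
    """A sampler or pipeline configuration violates its constraints."""


class SamplingError(GrnBenchError):
    """A network sampler could not produce a valid graph within its retry budget."""


class ParseError(GrnBenchError):
    """A delimited input file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyNetworkError(GrnBenchError):
    """An operation produced or received a network with no usable nodes."""


class DegenerateNetworkError(GrnBenchError):
    """Post-processing left fewer than two nodes."""


class ModeMismatchError(GrnBenchError):
    """Directed/undirected evaluation mode is incompatible with the input."""


class MissingSignError(GrnBenchError):
    """A regulatory edge lacks the activation/repression sign required."""


class IntegrationError(GrnBenchError):
    """The stochastic simulation produced a non-finite state."""


class InsufficientDataError(GrnBenchError):
    """Too few cells (or genes) for the requested inference."""


class ConsistencyError(GrnBenchError):
    """Cross-file or cross-table identifiers disagree."""


class UndefinedMetricError(GrnBenchError):
    """A topological metric is undefined on this input (e.g. n < 3)."""


class AggregationError(GrnBenchError):
    """Evaluation records cannot be aggregated as requested."""


class ConvergenceError(GrnBenchError):
    """An iterative numerical routine failed to converge."""
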