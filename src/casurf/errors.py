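"""Exception hierarchy for the casurf pipeline."""


class CasurfError(Exception):
    """Base class for all casurf errors."""


class ParseError(CasurfError):
    """A structural model or matrix file could not be parsed."""


class EmptyStructureError(CasurfError):
    """No protein residues were found in the input."""


class FormatError(CasurfError):
    """A file parsed but violated the expected format contract."""


class MappingError(CasurfError):
    """Residue renumbering or profile mapping failed."""


class DegenerateGeometryError(CasurfError):
    """Too few or degenerate (coplanar/collinear) coordinates for tessellation."""


class EmptyGraphError(CasurfError):
    """A residue graph with no usable nodes or edges was requested."""


class ConvergenceError(CasurfError):
    """Power iteration failed to converge within the iteration budget."""

    def __init__(self, message: str, iterations: int, residual: float):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual


class DegenerateSplitError(CasurfError):
    """Two-cluster split is undefined (all scores identical)."""


class ScoringError(CasurfError):
    """Patch scoring is undefined (e.g. empty non-patch surface)."""
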