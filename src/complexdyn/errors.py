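"""Exception types shared across the package."""


class ComplexDynError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(ComplexDynError):
    """A PDB record could not be parsed; message names the line number."""


class TopologyMismatchError(ComplexDynError):
    """A trajectory model has missing/extra atoms relative to model 1."""

    def __init__(self, missing=(), extra=(), model=None):
        self.missing = tuple(missing)
        self.extra = tuple(extra)
        self.model = model
        parts = [f"model {model}: topology mismatch"]
        if self.missing:
            parts.append(f"missing atoms {list(self.missing)}")
        if self.extra:
            parts.append(f"extra atoms {list(self.extra)}")
        super().__init__("; ".join(parts))


class FormatOverflowError(ComplexDynError):
    """A coordinate does not fit the fixed-width PDB coordinate field."""


class EmptySelectionError(ComplexDynError):
    """A selection resolved to no atoms; analyses never run on nothing."""


class SelectionError(ComplexDynError):
    """A selection referenced chains/residues absent from the structure."""


class UnderdeterminedSuperpositionError(ComplexDynError):
    """Fewer than 3 atoms, or a degenerate (collinear) coordinate set."""


class ConvergenceError(ComplexDynError):
    """Iterative mean-structure alignment failed to converge."""

    def __init__(self, final_shift, max_iter):
        self.final_shift = final_shift
        self.max_iter = max_iter
        super().__init__(
            f"mean-structure alignment did not converge after {max_iter} "
            f"iterations (final mean shift {final_shift:.3e} A)"
        )


class BlockTooLargeError(ComplexDynError):
    """Coarsening block exceeds the snapshot count."""


class HydrogenModeError(ComplexDynError):
    """Explicit-hydrogen analysis requested on a hydrogen-free structure."""


class EmptyPeriodError(ComplexDynError):
    """A requested time period contains no snapshots."""


class GridMismatchError(ComplexDynError):
    """Two occupancy grids have different shapes."""


class InsufficientDataError(ComplexDynError):
    """Too few snapshots for the requested decomposition."""


class ModeRankError(ComplexDynError):
    """Requested principal-component rank exceeds the available modes."""


class SimSpecError(ComplexDynError):
    """A synthetic-trajectory specification is internally inconsistent."""


class GeometryError(ComplexDynError):
    """Generated reference geometry is invalid (e.g. overlapping chains)."""
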