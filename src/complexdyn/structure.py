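"""Multi-model PDB input/output, structure/trajectory containers, selections.

The trajectory model is deliberately minimal: one topology (atom identities
from the first MODEL) shared by every frame, frames stored as plain coordinate
arrays in angstroms, and a uniform time step in nanoseconds supplied by the
caller because the PDB format carries no time information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import (
    EmptySelectionError,
    FormatOverflowError,
    PDBParseError,
    TopologyMismatchError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "read_pdb",
    "write_pdb",
    "resolve_selection",
    "snapshot_count",
]

#: Backbone atom names (protein main chain).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Residue names treated as water and skipped by default.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology.

    The identity key ``(chain, resseq, icode, name)`` must be unique within a
    model; it is how atoms are matched across trajectory frames.
    """

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    icode: str = ""
    coord: tuple[float, float, float] = (0.0, 0.0, 0.0)
    element: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.resseq, self.icode, self.name)

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain, self.resseq)


@dataclass
class Structure:
    """An ordered set of atoms representing one snapshot."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")
        seen: set[tuple] = set()
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.coord):
                raise ValueError(f"non-finite coordinate on atom {a.key}")
            if a.key in seen:
                raise ValueError(f"duplicate atom key {a.key}")
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in angstroms."""
        return np.asarray([a.coord for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of this structure with coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape {(len(self.atoms), 3)}")
        atoms = [replace(a, coord=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, label if label is not None else self.label)

    def atom_index(self) -> dict[tuple, int]:
        """Map atom key -> position in the atom list."""
        return {a.key: i for i, a in enumerate(self.atoms)}

    @property
    def chains(self) -> tuple[str, ...]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return tuple(out)

    def residues(self, chain: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered (chain, resseq, resname) residue identifiers."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            rid = (a.chain, a.resseq)
            if rid not in seen:
                seen.add(rid)
                out.append((a.chain, a.resseq, a.resname))
        return out


@dataclass
class Trajectory:
    """Ordered snapshots sharing one topology.

    Parameters
    ----------
    topology
        Atom identities; coordinates of the topology itself are those of the
        first frame.
    frames
        Array of shape (n_frames, n_atoms, 3), angstroms.
    dt_ns
        Time between consecutive snapshots in nanoseconds.
    t0_ns
        Time of the first snapshot in nanoseconds.
    """

    topology: Structure
    frames: np.ndarray
    dt_ns: float = 1.0
    t0_ns: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"frames must have shape (n, {len(self.topology)}, 3), "
                f"got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one snapshot")
        if not self.dt_ns > 0:
            raise ValueError("dt_ns must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def __len__(self) -> int:
        return self.n_frames

    @property
    def times_ns(self) -> np.ndarray:
        return self.t0_ns + self.dt_ns * np.arange(self.n_frames)

    @property
    def total_ns(self) -> float:
        """Simulated span covered by the snapshots (first to last)."""
        return float(self.dt_ns * (self.n_frames - 1))

    def snapshot(self, i: int) -> Structure:
        """Materialize frame *i* as a Structure."""
        return self.topology.with_coords(self.frames[i], label=f"frame {i}")


def snapshot_count(total_ns: float, save_interval_ns: float) -> int:
    """Snapshots written by a run of ``total_ns`` saved every
    ``save_interval_ns``, counting the initial snapshot at t=0.

    A 2 us run saved every 2 ns yields 1001 snapshots.
    """
    if total_ns < 0 or save_interval_ns <= 0:
        raise ValueError("durations must be positive")
    n, rem = divmod(total_ns, save_interval_ns)
    if not math.isclose(rem, 0.0, abs_tol=1e-9 * save_interval_ns):
        raise ValueError("total_ns must be a multiple of the save interval")
    return int(round(n)) + 1


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection.

    ``atom_class`` is one of ``all``, ``heavy``, ``backbone`` (N, CA, C, O) or
    ``calpha``. ``residue_range`` is an inclusive (start, end) applied to all
    chains, or a mapping chain -> (start, end).
    """

    chains: frozenset[str] | None = None
    residue_range: tuple[int, int] | Mapping[str, tuple[int, int]] | None = None
    atom_class: str = "all"

    def __post_init__(self) -> None:
        if self.atom_class not in ("all", "heavy", "backbone", "calpha"):
            raise ValueError(f"unknown atom_class {self.atom_class!r}")
        if self.chains is not None:
            object.__setattr__(self, "chains", frozenset(self.chains))


def _in_range(a: AtomRecord, rng) -> bool:
    if rng is None:
        return True
    if isinstance(rng, Mapping):
        sub = rng.get(a.chain)
        if sub is None:
            return True
        lo, hi = sub
    else:
        lo, hi = rng
    return lo <= a.resseq <= hi


def resolve_selection(struct: Structure, sel: Selection) -> np.ndarray:
    """Resolve a Selection to an ordered array of atom indices.

    Raises :class:`EmptySelectionError` if nothing matches, so an analysis can
    never silently run on zero atoms.
    """
    idx: list[int] = []
    for i, a in enumerate(struct.atoms):
        if sel.chains is not None and a.chain not in sel.chains:
            continue
        if not _in_range(a, sel.residue_range):
            continue
        if sel.atom_class == "heavy" and a.element.upper() == "H":
            continue
        if sel.atom_class == "backbone" and a.name not in BACKBONE_ATOMS:
            continue
        if sel.atom_class == "calpha" and a.name != "CA":
            continue
        idx.append(i)
    if not idx:
        raise EmptySelectionError(f"selection {sel} matched no atoms")
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# PDB reading


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # Two-letter elements in proteins are rare; default to first alpha char.
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record too short")
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # serial is cosmetic; never fail on it
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or " "
    try:
        resseq = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from exc
    icode = line[26].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed coordinate field {line[30:54]!r}"
        ) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    if altloc not in ("", "A"):  # keep only the primary alternate location
        return None
    return AtomRecord(
        serial=serial,
        name=name,
        resname=resname,
        chain=chain,
        resseq=resseq,
        icode=icode,
        coord=(x, y, z),
        element=element,
    )


def read_pdb(
    source,
    dt_ns: float = 1.0,
    t0_ns: float = 0.0,
    include_het: bool = False,
    label: str = "",
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    One frame per MODEL (a file with no MODEL records is a single implicit
    model). The topology comes from the first model; later models are matched
    atom-by-atom on ``(chain, resseq, icode, name)`` and must contain exactly
    the same atoms. Alternate locations other than blank/"A" are dropped;
    HETATM records and waters are skipped unless ``include_het`` is set.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()

    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model_record = False
    for lineno, line in enumerate(lines, start=1):
        rec_name = line[:6].strip()
        if rec_name == "MODEL":
            saw_model_record = True
            in_model = True
            current = []
        elif rec_name == "ENDMDL":
            in_model = False
            models.append(current)
            current = []
        elif rec_name in ("ATOM", "HETATM"):
            if rec_name == "HETATM" and not include_het:
                continue
            atom = _parse_atom_line(line, lineno)
            if atom is None:  # non-primary altloc
                continue
            if atom.resname in WATER_RESNAMES and not include_het:
                continue
            current.append(atom)
            if not saw_model_record:
                in_model = True
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError("no ATOM records found")

    topology = Structure(models[0], label=label)
    keys = [a.key for a in topology.atoms]
    key_set = set(keys)
    frames = np.empty((len(models), len(keys), 3), dtype=float)
    frames[0] = topology.coords
    for mi, model in enumerate(models[1:], start=2):
        lookup = {a.key: a for a in model}
        missing = [k for k in keys if k not in lookup]
        extra = [a.key for a in model if a.key not in key_set]
        if missing or extra:
            raise TopologyMismatchError(missing=missing, extra=extra, model=mi)
        frames[mi - 1] = [lookup[k].coord for k in keys]
    return Trajectory(topology=topology, frames=frames, dt_ns=dt_ns, t0_ns=t0_ns)


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom_name(name: str, element: str) -> str:
    # Names of one-letter elements start in column 14 unless 4 chars long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def _atom_line(a: AtomRecord, serial: int, coord: np.ndarray) -> str:
    x, y, z = coord
    for c in (x, y, z):
        if abs(c) >= 10000.0:
            raise FormatOverflowError(
                f"coordinate {c:.3f} on atom {a.key} exceeds the PDB field width"
            )
    return (
        f"ATOM  {serial:>5d} {_format_atom_name(a.name, a.element)}"
        f" {a.resname:<3s} {a.chain:1s}{a.resseq:>4d}{a.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(traj: Trajectory | Structure, sink) -> None:
    """Write a trajectory (or single structure) as a multi-model PDB file.

    Coordinates are formatted to 3 decimals per PDB v3.3; values of 10000 A or
    more raise :class:`FormatOverflowError`.
    """
    if isinstance(traj, Structure):
        traj = Trajectory(topology=traj, frames=traj.coords[None, :, :])

    own = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w")
        own = True
    try:
        for fi in range(traj.n_frames):
            sink.write(f"MODEL     {fi + 1:>4d}\n")
            serial = 0
            prev_chain = None
            for a, coord in zip(traj.topology.atoms, traj.frames[fi]):
                if prev_chain is not None and a.chain != prev_chain:
                    sink.write(f"TER   {serial + 1:>5d}\n")
                    serial += 1
                serial += 1
                sink.write(_atom_line(a, serial, coord) + "\n")
                prev_chain = a.chain
            sink.write(f"TER   {serial + 1:>5d}\n")
            sink.write("ENDMDL\n")
        sink.write("END\n")
    finally:
        if own:
            sink.close()
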