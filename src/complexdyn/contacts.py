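"""Hydrogen bonds, salt bridges, interface residues, and their persistence.

Detection is geometric, in the style of occupancy analyses run with VMD:
a salt bridge is a side-chain oxygen of an acidic residue within 3.2 A of a
side-chain nitrogen of a basic residue; a hydrogen bond is a donor-acceptor
heavy-atom pair within a distance cutoff, with a D-H...A near-linearity test
when explicit hydrogens are available. Per-snapshot detections aggregate into
residue-pair occupancy fractions, which are tiered against the thresholds
used for a 2 us trajectory: stable (>5%, i.e. >100 ns), >1% (>20 ns) and
>0.1% (>2 ns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import HydrogenModeError, SelectionError
from .structure import AtomRecord, Structure, Trajectory

__all__ = [
    "ContactCriteria",
    "PersistenceRecord",
    "DistanceSeries",
    "hydrogen_bonds",
    "salt_bridges",
    "persistence",
    "interface_residues",
    "distance_series",
    "tier_for_fraction",
    "TIER_EDGES",
]

# side-chain donor/acceptor heavy atoms by residue; backbone N (non-proline)
# donates and backbone O accepts for every residue
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}

ACIDIC_OXYGENS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_NITROGENS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
HIS_NITROGENS: tuple[str, ...] = ("ND1", "NE2")

STANDARD_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: occupancy-fraction tier edges (strict "more than"), highest first
TIER_EDGES: tuple[tuple[float, str], ...] = (
    (0.05, "stable>=5%"),
    (0.01, ">=1%"),
    (0.001, ">=0.1%"),
)


def tier_for_fraction(fraction: float) -> str:
    """Map an occupancy fraction to its persistence tier (strict >)."""
    for edge, label in TIER_EDGES:
        if fraction > edge:
            return label
    return "below"


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric contact criteria.

    ``hb_da_cutoff`` defaults depend on ``hydrogen_mode``: 3.0 A when explicit
    hydrogens supply a D-H...A angle test, 3.5 A when only heavy atoms are
    available. ``hb_angle_cutoff`` is the allowed deviation of D-H...A from
    linearity in degrees. ``sb_cutoff`` is the acidic-O to basic-N distance.
    """

    hb_da_cutoff: float | None = None
    hb_angle_cutoff: float = 20.0
    sb_cutoff: float = 3.2
    hydrogen_mode: str = "heavy_only"
    include_his: bool = False

    def __post_init__(self) -> None:
        if self.hydrogen_mode not in ("explicit", "heavy_only"):
            raise ValueError("hydrogen_mode must be 'explicit' or 'heavy_only'")
        if self.hb_da_cutoff is None:
            object.__setattr__(
                self, "hb_da_cutoff", 3.0 if self.hydrogen_mode == "explicit" else 3.5
            )
        for v in (self.hb_da_cutoff, self.hb_angle_cutoff, self.sb_cutoff):
            if not v > 0:
                raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class PersistenceRecord:
    """A residue-residue interaction with its trajectory occupancy."""

    kind: str  # "hbond" | "saltbridge"
    res_a: tuple[str, int, str]  # (chain, resseq, resname)
    res_b: tuple[str, int, str]
    frames_present: int
    fraction: float
    duration_ns: float
    tier: str


@dataclass
class DistanceSeries:
    """Minimum inter-group distance per snapshot."""

    pair: tuple[tuple, tuple]
    times_ns: np.ndarray
    values: np.ndarray


# ---------------------------------------------------------------------------
# candidate typing (topology-level, computed once per structure/trajectory)


def _warn_nonstandard(top: Structure) -> None:
    odd = sorted({a.resname for a in top.atoms} - STANDARD_RESNAMES)
    if odd:
        warnings.warn(f"skipping donor/acceptor typing for non-standard residues {odd}")


def _donor_indices(top: Structure) -> list[int]:
    out = []
    for i, a in enumerate(top.atoms):
        if a.name == "N" and a.resname != "PRO":
            out.append(i)
        elif a.name in SIDECHAIN_DONORS.get(a.resname, ()):
            out.append(i)
    return out


def _acceptor_indices(top: Structure) -> list[int]:
    out = []
    for i, a in enumerate(top.atoms):
        if a.name == "O":
            out.append(i)
        elif a.name in SIDECHAIN_ACCEPTORS.get(a.resname, ()):
            out.append(i)
    return out


def _attached_hydrogens(top: Structure, coords: np.ndarray, donor_idx: list[int]) -> dict[int, list[int]]:
    """Hydrogens covalently attached to each donor (same residue, <1.25 A)."""
    hyd = [i for i, a in enumerate(top.atoms) if a.element.upper() == "H"]
    attached: dict[int, list[int]] = {d: [] for d in donor_idx}
    for h in hyd:
        ha = top.atoms[h]
        best, best_d = None, 1.25
        for d in donor_idx:
            da = top.atoms[d]
            if da.residue_id != ha.residue_id:
                continue
            dist = float(np.linalg.norm(coords[h] - coords[d]))
            if dist < best_d:
                best, best_d = d, dist
        if best is not None:
            attached[best].append(h)
    return attached


def _partition_masks(top: Structure, partition):
    """Per-atom chain-side arrays for inter-partition filtering (or None)."""
    if partition is None:
        return None
    chains_a, chains_b = (set(partition[0]), set(partition[1]))
    side = np.zeros(len(top), dtype=int)  # 0 = neither, 1 = A, 2 = B
    for i, a in enumerate(top.atoms):
        if a.chain in chains_a:
            side[i] = 1
        elif a.chain in chains_b:
            side[i] = 2
    return side


def _angle_deviation_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Deviation of the D-H...A angle from 180 degrees."""
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - ang


def _hbond_pairs(
    top: Structure,
    coords: np.ndarray,
    criteria: ContactCriteria,
    donors: list[int],
    acceptors: list[int],
    attached: dict[int, list[int]] | None,
    side: np.ndarray | None,
) -> list[tuple[int, int]]:
    if not donors or not acceptors:
        return []
    D = cdist(coords[donors], coords[acceptors])
    out: list[tuple[int, int]] = []
    for di, ai in zip(*np.nonzero(D <= criteria.hb_da_cutoff)):
        d, a = donors[di], acceptors[ai]
        if top.atoms[d].residue_id == top.atoms[a].residue_id:
            continue
        if side is not None and {side[d], side[a]} != {1, 2}:
            continue
        if criteria.hydrogen_mode == "explicit":
            ok = any(
                _angle_deviation_deg(coords[d], coords[h], coords[a])
                <= criteria.hb_angle_cutoff
                for h in attached.get(d, ())
            )
            if not ok:
                continue
        out.append((d, a))
    return out


def _saltbridge_pairs(
    top: Structure,
    coords: np.ndarray,
    criteria: ContactCriteria,
    acid_o: list[int],
    base_n: list[int],
    side: np.ndarray | None,
) -> list[tuple[int, int]]:
    if not acid_o or not base_n:
        return []
    D = cdist(coords[acid_o], coords[base_n])
    out: list[tuple[int, int]] = []
    for oi, ni in zip(*np.nonzero(D <= criteria.sb_cutoff)):
        o, n = acid_o[oi], base_n[ni]
        if side is not None and {side[o], side[n]} != {1, 2}:
            continue
        out.append((o, n))
    return out


def _acid_base_indices(top: Structure, criteria: ContactCriteria):
    acid = [
        i
        for i, a in enumerate(top.atoms)
        if a.name in ACIDIC_OXYGENS.get(a.resname, ())
    ]
    basic_map = dict(BASIC_NITROGENS)
    if criteria.include_his:
        basic_map["HIS"] = HIS_NITROGENS
    base = [i for i, a in enumerate(top.atoms) if a.name in basic_map.get(a.resname, ())]
    return acid, base


# ---------------------------------------------------------------------------
# public snapshot-level API


def hydrogen_bonds(
    snapshot: Structure,
    criteria: ContactCriteria | None = None,
    partition: tuple | None = None,
) -> list[tuple[AtomRecord, AtomRecord]]:
    """Hydrogen bonds in one snapshot as (donor, acceptor) atom pairs.

    ``partition`` is an optional (chains_a, chains_b) pair restricting the
    search to inter-partition bonds. In ``explicit`` mode the structure must
    carry hydrogens (a D-H...A linearity test is applied); ``heavy_only``
    mode uses the donor-acceptor distance alone.
    """
    criteria = criteria or ContactCriteria()
    coords = snapshot.coords
    donors = _donor_indices(snapshot)
    acceptors = _acceptor_indices(snapshot)
    _warn_nonstandard(snapshot)
    attached = None
    if criteria.hydrogen_mode == "explicit":
        if not any(a.element.upper() == "H" for a in snapshot.atoms):
            raise HydrogenModeError(
                "explicit hydrogen mode requested but the structure has no "
                "hydrogens; use hydrogen_mode='heavy_only'"
            )
        attached = _attached_hydrogens(snapshot, coords, donors)
    side = _partition_masks(snapshot, partition)
    pairs = _hbond_pairs(snapshot, coords, criteria, donors, acceptors, attached, side)
    return [(snapshot.atoms[d], snapshot.atoms[a]) for d, a in pairs]


def salt_bridges(
    snapshot: Structure,
    criteria: ContactCriteria | None = None,
    partition: tuple | None = None,
) -> list[tuple[AtomRecord, AtomRecord]]:
    """Salt bridges in one snapshot as (acidic O, basic N) atom pairs.

    Side-chain oxygens of ASP/GLU against side-chain nitrogens of LYS/ARG
    (plus HIS when ``include_his``), within ``sb_cutoff`` (3.2 A default).
    """
    criteria = criteria or ContactCriteria()
    acid, base = _acid_base_indices(snapshot, criteria)
    side = _partition_masks(snapshot, partition)
    pairs = _saltbridge_pairs(snapshot, snapshot.coords, criteria, acid, base, side)
    return [(snapshot.atoms[o], snapshot.atoms[n]) for o, n in pairs]


def persistence(
    traj: Trajectory,
    criteria: ContactCriteria | None = None,
    partition: tuple | None = None,
    kinds: tuple[str, ...] = ("hbond", "saltbridge"),
) -> list[PersistenceRecord]:
    """Aggregate snapshot contacts into residue-pair occupancy records.

    A residue pair counts as present in a snapshot if any qualifying atom
    pair exists (no multiplicity). ``duration_ns`` is
    ``fraction * n_snapshots * dt_ns``, so with 2 ns sampling over 2 us the
    tier edges fall at 100, 20 and 2 ns. Pairs never formed are absent.
    """
    criteria = criteria or ContactCriteria()
    top = traj.topology
    _warn_nonstandard(top)
    donors = _donor_indices(top)
    acceptors = _acceptor_indices(top)
    acid, base = _acid_base_indices(top, criteria)
    side = _partition_masks(top, partition)
    attached = None
    if "hbond" in kinds and criteria.hydrogen_mode == "explicit":
        if not any(a.element.upper() == "H" for a in top.atoms):
            raise HydrogenModeError(
                "explicit hydrogen mode requested but the topology has no "
                "hydrogens; use hydrogen_mode='heavy_only'"
            )
        attached = _attached_hydrogens(top, traj.frames[0], donors)

    counts: dict[tuple[str, tuple, tuple], int] = {}
    for fi in range(traj.n_frames):
        coords = traj.frames[fi]
        present: set[tuple[str, tuple, tuple]] = set()
        if "hbond" in kinds:
            for d, a in _hbond_pairs(top, coords, criteria, donors, acceptors, attached, side):
                present.add(("hbond",) + _pair_key(top, d, a, side))
        if "saltbridge" in kinds:
            for o, n in _saltbridge_pairs(top, coords, criteria, acid, base, side):
                present.add(("saltbridge",) + _pair_key(top, o, n, side))
        for key in present:
            counts[key] = counts.get(key, 0) + 1

    n = traj.n_frames
    total_ns = n * traj.dt_ns
    records = []
    for (kind, ra, rb), c in sorted(counts.items()):
        frac = c / n
        records.append(
            PersistenceRecord(
                kind=kind,
                res_a=ra,
                res_b=rb,
                frames_present=c,
                fraction=frac,
                duration_ns=frac * total_ns,
                tier=tier_for_fraction(frac),
            )
        )
    return records


def _pair_key(top: Structure, i: int, j: int, side: np.ndarray | None):
    """Canonical residue-pair key: side A first under a partition, else
    sorted by (chain, resseq)."""
    ai, aj = top.atoms[i], top.atoms[j]
    ra = (ai.chain, ai.resseq, ai.resname)
    rb = (aj.chain, aj.resseq, aj.resname)
    if side is not None:
        if side[i] == 2:
            ra, rb = rb, ra
        return (ra, rb)
    return tuple(sorted((ra, rb)))


def interface_residues(
    snapshot: Structure,
    chains_a,
    chains_b,
    cutoff: float,
) -> tuple[list[tuple[str, int, str]], list[tuple[str, int, str]]]:
    """Residues of each side with any heavy atom strictly within ``cutoff``
    of a heavy atom of the other side.

    The published maps use 6, 5 and 4 A versions of this cutoff; results are
    nested (a tighter cutoff always yields a subset).
    """
    known = {a.chain for a in snapshot.atoms}
    for c in set(chains_a) | set(chains_b):
        if c not in known:
            raise SelectionError(f"unknown chain id {c!r}")
    side = _partition_masks(snapshot, (set(chains_a), set(chains_b)))
    heavy = np.asarray([a.element.upper() != "H" for a in snapshot.atoms])
    ia = np.nonzero((side == 1) & heavy)[0]
    ib = np.nonzero((side == 2) & heavy)[0]
    if ia.size == 0 or ib.size == 0:
        raise SelectionError("both chain sets must contain heavy atoms")
    coords = snapshot.coords
    D = cdist(coords[ia], coords[ib])
    close = D < cutoff
    res_a: list[tuple[str, int, str]] = []
    for k in ia[np.any(close, axis=1).nonzero()[0]]:
        a = snapshot.atoms[k]
        rid = (a.chain, a.resseq, a.resname)
        if rid not in res_a:
            res_a.append(rid)
    res_b: list[tuple[str, int, str]] = []
    for k in ib[np.any(close, axis=0).nonzero()[0]]:
        a = snapshot.atoms[k]
        rid = (a.chain, a.resseq, a.resname)
        if rid not in res_b:
            res_b.append(rid)
    return res_a, res_b


def distance_series(traj: Trajectory, group_a, group_b) -> DistanceSeries:
    """Per-snapshot minimum distance between two atom groups.

    Groups are lists of atom keys ``(chain, resseq, name)`` (insertion codes
    assumed blank) or full 4-tuples. Single-atom groups give the plain
    Euclidean distance series.
    """
    index = traj.topology.atom_index()

    def lookup(keys):
        out = []
        for k in keys:
            kk = (k[0], k[1], "", k[2]) if len(k) == 3 else tuple(k)
            if kk not in index:
                raise KeyError(f"atom key {k} not in topology")
            out.append(index[kk])
        return np.asarray(out, dtype=int)

    ia, ib = lookup(group_a), lookup(group_b)
    values = np.empty(traj.n_frames)
    for fi in range(traj.n_frames):
        values[fi] = cdist(traj.frames[fi][ia], traj.frames[fi][ib]).min()
    return DistanceSeries(
        pair=(tuple(map(tuple, group_a)), tuple(map(tuple, group_b))),
        times_ns=traj.times_ns,
        values=values,
    )
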