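"""Backbone phi/psi series and Ramachandran-occupancy comparison.

Dihedrals follow the IUPAC convention: phi(i) = C(i-1)-N(i)-CA(i)-C(i),
psi(i) = N(i)-CA(i)-C(i)-N(i+1), sign by the right-hand rule, reported in
degrees on (-180, 180]. Angles undefined at chain termini are explicitly
absent, never reported as zero. Occupancies over trajectory periods are
normalized 2D histograms on the (phi, psi) torus, compared with the
normalized Jensen-Shannon divergence (base 2, range [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .errors import EmptyPeriodError, GridMismatchError
from .structure import Trajectory

__all__ = [
    "DihedralSeries",
    "RamaOccupancy",
    "dihedral_angle",
    "phi_psi",
    "rama_occupancy",
    "occupancy_divergence",
]


def dihedral_angle(p0, p1, p2, p3) -> float | np.ndarray:
    """Signed dihedral of four points (degrees, (-180, 180]).

    Accepts single points (3,) or stacked frames (n, 3); the standard
    atan2 cross-product formula.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(-y, x))
    # boundary maps to +180, never -180
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return float(ang) if ang.ndim == 0 else ang


@dataclass
class DihedralSeries:
    """phi/psi time series for one residue; ``None`` marks an angle undefined
    at a chain terminus."""

    residue: tuple[str, int, str]
    times_ns: np.ndarray
    phi: np.ndarray | None
    psi: np.ndarray | None


def _backbone_map(traj: Trajectory) -> dict[tuple[str, int], dict[str, int]]:
    out: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(traj.topology.atoms):
        if a.name in ("N", "CA", "C"):
            out.setdefault(a.residue_id, {})[a.name] = i
    return out


def phi_psi(traj: Trajectory, residue: tuple[str, int]) -> DihedralSeries:
    """phi/psi series for ``residue`` = (chain, resseq) over all snapshots."""
    chain, resseq = residue
    bb = _backbone_map(traj)
    order = [rid for rid in bb if rid[0] == chain]
    if (chain, resseq) not in bb:
        raise KeyError(f"residue {residue} has no backbone atoms")
    pos = order.index((chain, resseq))
    this = bb[(chain, resseq)]
    for name in ("N", "CA", "C"):
        if name not in this:
            raise KeyError(f"residue {residue} is missing backbone atom {name}")

    prev_c = None
    if pos > 0:
        prev_c = bb[order[pos - 1]].get("C")
    next_n = None
    if pos < len(order) - 1:
        next_n = bb[order[pos + 1]].get("N")

    F = traj.frames
    phi = None
    if prev_c is not None:
        phi = dihedral_angle(F[:, prev_c], F[:, this["N"]], F[:, this["CA"]], F[:, this["C"]])
        phi = np.atleast_1d(phi)
    psi = None
    if next_n is not None:
        psi = dihedral_angle(F[:, this["N"]], F[:, this["CA"]], F[:, this["C"]], F[:, next_n])
        psi = np.atleast_1d(psi)

    resname = next(
        a.resname for a in traj.topology.atoms if a.residue_id == (chain, resseq)
    )
    return DihedralSeries(
        residue=(chain, resseq, resname), times_ns=traj.times_ns, phi=phi, psi=psi
    )


@dataclass
class RamaOccupancy:
    """Normalized (phi, psi) histogram on a g x g grid over (-180, 180]^2."""

    grid: int
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.grid, self.grid):
            raise ValueError("mass must be grid x grid")
        if np.any(self.mass < 0) or not np.isclose(self.mass.sum(), 1.0, atol=1e-9):
            raise ValueError("mass must be a probability distribution")


def _bin_angles(angles: np.ndarray, grid: int) -> np.ndarray:
    width = 360.0 / grid
    idx = np.floor((np.asarray(angles) + 180.0) / width).astype(int)
    return np.clip(idx, 0, grid - 1)  # +180 falls in the last bin


def rama_occupancy(
    series: DihedralSeries,
    period: tuple[float, float] | None = None,
    grid_size: int = 36,
) -> RamaOccupancy:
    """Occupancy histogram of (phi, psi) within a time period (inclusive)."""
    if series.phi is None or series.psi is None:
        raise ValueError("residue lacks a defined phi or psi (chain terminus)")
    mask = np.ones(len(series.times_ns), dtype=bool)
    if period is not None:
        t0, t1 = period
        mask = (series.times_ns >= t0) & (series.times_ns <= t1)
    if not mask.any():
        raise EmptyPeriodError(f"period {period} contains no snapshots")
    pi = _bin_angles(series.phi[mask], grid_size)
    si = _bin_angles(series.psi[mask], grid_size)
    mass = np.zeros((grid_size, grid_size))
    np.add.at(mass, (pi, si), 1.0)
    mass /= mass.sum()
    return RamaOccupancy(grid=grid_size, mass=mass)


def occupancy_divergence(a: RamaOccupancy, b: RamaOccupancy) -> float:
    """Jensen-Shannon divergence between two occupancies, base 2, in [0, 1]."""
    if a.grid != b.grid:
        raise GridMismatchError(f"grids differ: {a.grid} vs {b.grid}")
    js = jensenshannon(a.mass.ravel(), b.mass.ravel(), base=2)
    if np.isnan(js):  # identical distributions can produce 0/0 inside scipy
        return 0.0
    return float(js**2)
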