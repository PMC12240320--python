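"""Essential dynamics: Cα covariance PCA and the dynamic cross-correlation
matrix (DCCM).

After superposing every snapshot onto the converged mean structure, the
3N-dimensional covariance matrix of the selected Cα coordinates is
diagonalized. Leading eigenvectors are the collective modes; eigenvalues (A^2)
are their variances, and per-snapshot projections give the motion along each
mode. The DCCM is the normalized covariance of per-residue displacement
vectors: +1 for fully correlated, -1 for fully anti-correlated motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ModeRankError
from .structure import Selection, Trajectory, resolve_selection
from .superpose import align_to_mean

__all__ = ["ModeDecomposition", "CrossCorrelation", "pca", "dccm", "mode_mobility"]


@dataclass
class ModeDecomposition:
    """Eigendecomposition of the Cα displacement covariance."""

    residues: list[tuple[str, int]]
    eigenvalues: np.ndarray  # descending, A^2
    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal columns
    variance_fraction: np.ndarray
    projections: np.ndarray  # (n_snapshots, n_modes)
    times_ns: np.ndarray
    residue_mobility: np.ndarray  # per-residue displacement of mode 1

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.size)


@dataclass
class CrossCorrelation:
    """Residue-residue dynamic cross-correlation matrix in [-1, 1]."""

    residues: list[tuple[str, int]]
    values: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.residues)


def _ca_indices(traj: Trajectory, sel: Selection | None) -> np.ndarray:
    if sel is None:
        sel = Selection(atom_class="calpha")
    idx = resolve_selection(traj.topology, sel)
    idx = np.asarray([i for i in idx if traj.topology.atoms[i].name == "CA"], dtype=int)
    if idx.size == 0:
        raise ValueError("selection resolves to no CA atoms")
    return idx


def pca(
    traj: Trajectory,
    sel: Selection | None = None,
    stride_ns: float | None = None,
) -> ModeDecomposition:
    """Principal component analysis of Cα coordinates.

    ``stride_ns`` subsamples snapshots at that time interval before the
    decomposition (e.g. every 20 ns of a 2 us run); projections are then
    reported for the strided snapshots. The covariance uses the population
    normalization (1/n), so each mode's projection variance equals its
    eigenvalue exactly.
    """
    idx = _ca_indices(traj, sel)
    frames = traj.frames
    times = traj.times_ns
    if stride_ns is not None:
        step = max(1, int(round(stride_ns / traj.dt_ns)))
        frames = frames[::step]
        times = times[::step]
    n = frames.shape[0]
    if n < 3:
        raise InsufficientDataError(f"PCA needs >= 3 snapshots, got {n}")

    aligned, mean = align_to_mean(frames, idx)
    X = (aligned[:, idx, :] - mean[idx]).reshape(n, -1)  # (n, 3N)
    # SVD of the centered data: eigenvalues of (X^T X)/n
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = np.clip(S**2 / n, 0.0, None)
    eigenvectors = Vt.T
    # deterministic sign: largest-magnitude component positive
    for m in range(eigenvectors.shape[1]):
        peak = np.argmax(np.abs(eigenvectors[:, m]))
        if eigenvectors[peak, m] < 0:
            eigenvectors[:, m] *= -1
    projections = X @ eigenvectors
    total = eigenvalues.sum()
    variance_fraction = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    residues = [traj.topology.atoms[i].residue_id for i in idx]
    decomp = ModeDecomposition(
        residues=residues,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        variance_fraction=variance_fraction,
        projections=projections,
        times_ns=times,
        residue_mobility=np.zeros(len(residues)),
    )
    decomp.residue_mobility = mode_mobility(decomp, 1)
    return decomp


def mode_mobility(decomp: ModeDecomposition, mode: int) -> np.ndarray:
    """Per-residue displacement magnitude of a mode (1-based rank).

    The Euclidean norm of the mode's per-residue 3-vector, scaled by the
    square root of its eigenvalue, so the squared mobilities sum to the
    eigenvalue.
    """
    if not 1 <= mode <= decomp.n_modes:
        raise ModeRankError(f"mode {mode} out of range 1..{decomp.n_modes}")
    v = decomp.eigenvectors[:, mode - 1].reshape(-1, 3)
    return np.sqrt(decomp.eigenvalues[mode - 1]) * np.linalg.norm(v, axis=1)


def dccm(traj: Trajectory, sel: Selection | None = None) -> CrossCorrelation:
    """Dynamic cross-correlation matrix of Cα displacements.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) over frames superposed
    onto the converged mean. Residues with zero displacement variance get
    zero off-diagonal entries (with a warning) and 1 on the diagonal.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("DCCM needs >= 2 snapshots")
    idx = _ca_indices(traj, sel)
    aligned, mean = align_to_mean(traj.frames, idx)
    disp = aligned[:, idx, :] - mean[idx]  # (n, N, 3)
    inner = np.einsum("fia,fja->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} residue(s) have zero variance; rows zeroed")
    denom = np.sqrt(np.outer(np.where(zero, 1.0, var), np.where(zero, 1.0, var)))
    values = inner / denom
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, -1.0, 1.0)
    residues = [traj.topology.atoms[i].residue_id for i in idx]
    return CrossCorrelation(residues=residues, values=values)
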