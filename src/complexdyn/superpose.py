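"""Rigid-body superposition, RMSD matrices, and per-residue fluctuation.

RMSD between frames is always the superposition-minimized value (Kabsch):
translation and proper rotation are removed before the deviation is measured,
so a pure rigid motion scores zero. RMSF is measured about the trajectory
mean structure after an iterated alignment of every frame to that mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, UnderdeterminedSuperpositionError
from .structure import Selection, Structure, Trajectory, resolve_selection

__all__ = [
    "KabschResult",
    "RMSDMatrix",
    "FluctProfile",
    "kabsch",
    "rmsd_between",
    "rmsd_matrix",
    "align_to_mean",
    "rmsf",
    "classify_flexibility",
    "FLEX_CLASS_LABELS",
]


@dataclass(frozen=True)
class KabschResult:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    ``rotation @ (mobile - mobile_centroid) + translation`` reproduces the
    aligned mobile coordinates; ``rmsd`` is the minimized value in angstroms.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def kabsch(mobile: np.ndarray, target: np.ndarray) -> KabschResult:
    """Least-squares rigid superposition (proper rotations only).

    Reflections are excluded by flipping the sign of the smallest singular
    value when the raw solution has determinant -1, so a mirror-image pair
    retains a positive RMSD.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must both be (k, 3)")
    k = P.shape[0]
    if k < 3:
        raise UnderdeterminedSuperpositionError(f"need >= 3 atoms, got {k}")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq
    # collinear sets leave the rotation about the common axis undetermined
    for X in (Pc, Qc):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise UnderdeterminedSuperpositionError("degenerate (collinear) coordinates")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    aligned = Pc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - Qc) ** 2, axis=1))))
    translation = cq - R @ cp
    return KabschResult(rotation=R, translation=translation, rmsd=rmsd)


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return ``mobile`` after optimal superposition onto ``target``."""
    res = kabsch(mobile, target)
    return np.asarray(mobile) @ res.rotation.T + res.translation


def _pair_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return kabsch(a, b).rmsd


@dataclass
class RMSDMatrix:
    """All-vs-all frame RMSD matrix (the 2D-RMSD map)."""

    n: int
    values: np.ndarray
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n, self.n):
            raise ValueError("values must be n x n")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("RMSD entries must be finite and non-negative")


def rmsd_between(
    traj: Trajectory, i: int, j: int, sel: Selection | np.ndarray | None = None
) -> float:
    """Superposition-minimized RMSD between frames ``i`` and ``j``."""
    idx = _resolve(traj.topology, sel)
    if i == j:
        return 0.0
    return _pair_rmsd(traj.frames[i][idx], traj.frames[j][idx])


def _resolve(top: Structure, sel) -> np.ndarray:
    if sel is None:
        return np.arange(len(top))
    if isinstance(sel, Selection):
        return resolve_selection(top, sel)
    return np.asarray(sel, dtype=int)


def rmsd_matrix(
    frames,
    sel: Selection | np.ndarray | None = None,
    topology: Structure | None = None,
    times_ns=None,
) -> RMSDMatrix:
    """Pairwise superposed RMSD over frames.

    ``frames`` may be a :class:`Trajectory` or an (n, k, 3) array of
    coordinate sets (e.g. coarse-frame mean structures). A Selection requires
    a topology to resolve against.
    """
    if isinstance(frames, Trajectory):
        if topology is None:
            topology = frames.topology
        if times_ns is None:
            times_ns = frames.times_ns
        frames = frames.frames
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames for an RMSD matrix")
    if isinstance(sel, Selection):
        if topology is None:
            raise ValueError("a Selection needs a topology to resolve against")
        idx = resolve_selection(topology, sel)
    elif sel is None:
        idx = np.arange(frames.shape[1])
    else:
        idx = np.asarray(sel, dtype=int)
    sub = frames[:, idx, :]
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _pair_rmsd(sub[i], sub[j])
    return RMSDMatrix(
        n=n,
        values=out,
        times_ns=None if times_ns is None else np.asarray(times_ns, dtype=float),
    )


def align_to_mean(
    frames: np.ndarray,
    align_idx: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all frames onto their converged mean structure.

    Frames are first aligned (via ``align_idx`` atoms) to frame 0, the mean is
    formed, frames re-aligned to the mean, and the cycle repeated until the
    mean moves less than ``tol`` (RMS over align atoms, angstroms).

    Returns (aligned_frames, mean) where the rigid transforms fitted on the
    align atoms are applied to all atoms.
    """
    frames = np.asarray(frames, dtype=float)
    aligned = np.empty_like(frames)
    reference = frames[0][align_idx]
    for fi in range(frames.shape[0]):
        res = kabsch(frames[fi][align_idx], reference)
        aligned[fi] = frames[fi] @ res.rotation.T + res.translation
    mean = aligned.mean(axis=0)
    shift = np.inf
    for _ in range(max_iter):
        ref = mean[align_idx]
        for fi in range(frames.shape[0]):
            res = kabsch(aligned[fi][align_idx], ref)
            aligned[fi] = aligned[fi] @ res.rotation.T + res.translation
        new_mean = aligned.mean(axis=0)
        shift = float(
            np.sqrt(np.mean(np.sum((new_mean[align_idx] - ref) ** 2, axis=1)))
        )
        mean = new_mean
        if shift < tol:
            return aligned, mean
    raise ConvergenceError(final_shift=shift, max_iter=max_iter)


#: Ordered relative-RMSF flexibility classes with their map colors.
FLEX_CLASS_LABELS = (
    "<0.5 (black)",
    "[0.5,1) (blue)",
    "[1,1.5) (light blue)",
    "[1.5,2) (light green)",
    "[2,2.5) (yellow)",
    "[2.5,3) (orange)",
    ">=3.0 (red)",
)

_FLEX_EDGES = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])


@dataclass
class FluctProfile:
    """Per-residue RMSF with relative (mean-normalized) values and classes."""

    residues: list[tuple[str, int]]
    rmsf: np.ndarray
    relative: np.ndarray = field(default=None)  # type: ignore[assignment]
    flex_class: list[str] | None = None

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be non-negative")
        if self.relative is None:
            mean = self.rmsf.mean()
            self.relative = self.rmsf / mean if mean > 0 else np.zeros_like(self.rmsf)
        else:
            self.relative = np.asarray(self.relative, dtype=float)


def rmsf(
    traj: Trajectory,
    sel: Selection | None = None,
    align_sel: Selection | None = None,
    reference: str = "mean",
) -> FluctProfile:
    """Per-residue Cα root-mean-square fluctuation.

    ``sel`` picks the residues profiled (their CA atoms); ``align_sel`` picks
    the atoms used for the frame alignment (defaults to the same CA set).
    ``reference`` is "mean" (iterated mean-structure alignment) or "initial"
    (fluctuation about the first frame after aligning everything to it).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if sel is None:
        sel = Selection(atom_class="calpha")
    ca_idx = resolve_selection(traj.topology, sel)
    # profile one CA per residue even if sel matched more
    ca_idx = np.asarray(
        [i for i in ca_idx if traj.topology.atoms[i].name == "CA"], dtype=int
    )
    if ca_idx.size == 0:
        raise ValueError("selection contains no CA atoms to profile")
    align_idx = ca_idx if align_sel is None else resolve_selection(traj.topology, align_sel)

    if reference == "mean":
        aligned, mean = align_to_mean(traj.frames, align_idx)
    elif reference == "initial":
        aligned = np.empty_like(traj.frames)
        ref = traj.frames[0][align_idx]
        for fi in range(traj.n_frames):
            res = kabsch(traj.frames[fi][align_idx], ref)
            aligned[fi] = traj.frames[fi] @ res.rotation.T + res.translation
        mean = traj.frames[0]
    else:
        raise ValueError("reference must be 'mean' or 'initial'")

    disp = aligned[:, ca_idx, :] - mean[ca_idx]
    values = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=0))
    residues = [traj.topology.atoms[i].residue_id for i in ca_idx]
    return FluctProfile(residues=residues, rmsf=values)


def classify_flexibility(profile: FluctProfile) -> FluctProfile:
    """Assign each residue its ordinal flexibility class.

    Bins on the relative (mean-normalized) RMSF: <0.5, [0.5,1), [1,1.5),
    [1.5,2), [2,2.5), [2.5,3), >=3 — interior bins left-closed/right-open.
    """
    bins = np.digitize(profile.relative, _FLEX_EDGES, right=False)
    profile.flex_class = [FLEX_CLASS_LABELS[b] for b in bins]
    return profile
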