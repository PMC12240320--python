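"""Synthetic two-chain complex trajectories with known ground truth.

Real MD trajectories of the complexes this package analyzes are not publicly
deposited, so every pipeline stage is exercised on generated trajectories in
which the answer is planted by construction:

* discrete conformational *states* — non-rigid displacement fields applied
  over prescribed snapshot intervals, rescaled so the superposition RMSD
  between state references equals a requested separation;
* per-residue isotropic Gaussian *fluctuations* of standard deviation sigma
  per coordinate (so the expected Cα RMSF is sigma*sqrt(3));
* inter-chain *contacts* held at a bound distance for a prescribed duty
  cycle of snapshots (random or contiguous-block schedules);
* collective *modes* — sinusoidal motion along orthonormal 3N vectors, each
  contributing an essential-dynamics eigenvalue of amplitude^2/2.

The default sampling mirrors a 2 us run recorded every 2 ns (1001 snapshots).
One integer seed makes the output bit-identical across runs; the noise and
the contact schedules draw from independently spawned generators so
:func:`ground_truth` can reproduce the schedules without re-simulating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import GeometryError, SimSpecError
from .structure import AtomRecord, Structure, Trajectory
from .superpose import kabsch

__all__ = [
    "PlantedState",
    "PlantedContact",
    "PlantedMode",
    "SimSpec",
    "build_reference",
    "simulate",
    "ground_truth",
    "localized_mode",
    "rigid_free_modes",
    "build_peptide",
]

CA_SPACING = 3.8  # consecutive CA-CA distance, A
CHAIN_SEPARATION = 30.0  # inter-chain axis offset, A


@dataclass
class PlantedState:
    """A conformational state active over snapshot intervals.

    ``intervals`` are half-open (start, end) snapshot index ranges. Either an
    explicit per-atom ``displacement`` field (n_atoms, 3) or a requested
    post-superposition ``separation`` (A) from the reference may be given; in
    the latter case a zero-mean zig-zag field is scaled to realize it.
    """

    intervals: list[tuple[int, int]]
    displacement: np.ndarray | None = None
    separation: float | None = None


@dataclass
class PlantedContact:
    """An inter-chain contact with a prescribed occupancy duty cycle.

    ``atom_a``/``atom_b`` are (chain, resseq, name) keys; atom_b is placed at
    the bound or unbound distance from atom_a each snapshot according to the
    schedule ("random": Bernoulli(duty) per snapshot; "block": one contiguous
    bound stretch of round(duty * n) snapshots).
    """

    atom_a: tuple[str, int, str]
    atom_b: tuple[str, int, str]
    duty: float
    bound: float = 2.9
    unbound: float = 12.0
    schedule: str = "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.duty <= 1.0:
            raise SimSpecError(f"duty cycle {self.duty} outside [0, 1]")
        if self.schedule not in ("random", "block"):
            raise SimSpecError(f"unknown schedule {self.schedule!r}")


@dataclass
class PlantedMode:
    """A collective mode: sinusoid along an orthonormal 3N vector."""

    vector: np.ndarray  # (3 * n_atoms,), unit norm
    amplitude: float  # A
    period: int  # snapshots per cycle
    phase: float = 0.0  # radians


@dataclass
class SimSpec:
    """Full specification of one synthetic complex trajectory.

    Defaults give a two-chain Cα complex (60 + 40 residues, roughly a GAP
    domain against a small GTPase in miniature) sampled like the reference
    protocol: 1001 snapshots at 2 ns. ``sigma`` is the per-coordinate
    fluctuation std in A, scalar or per-residue array over chain A then B.
    """

    n_res_a: int = 60
    n_res_b: int = 40
    backbone: str = "calpha_only"  # or "full_backbone"
    states: list[PlantedState] = field(default_factory=list)
    sigma: float | np.ndarray = 0.5
    contacts: list[PlantedContact] = field(default_factory=list)
    modes: list[PlantedMode] = field(default_factory=list)
    n_snapshots: int = 1001
    dt_ns: float = 2.0
    ar1: float = 0.0  # optional temporal correlation of the noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in ("calpha_only", "full_backbone"):
            raise SimSpecError(f"unknown backbone mode {self.backbone!r}")
        if self.n_snapshots < 1 or self.n_res_a < 1 or self.n_res_b < 1:
            raise SimSpecError("counts must be positive")
        if not 0.0 <= self.ar1 < 1.0:
            raise SimSpecError("ar1 must be in [0, 1)")
        for st in self.states:
            for a, b in st.intervals:
                if not 0 <= a < b <= self.n_snapshots:
                    raise SimSpecError(f"state interval ({a}, {b}) outside trajectory")
        if self.modes:
            V = np.stack([np.asarray(m.vector, dtype=float) for m in self.modes])
            G = V @ V.T
            if not np.allclose(G, np.eye(len(self.modes)), atol=1e-8):
                raise SimSpecError("mode vectors must be mutually orthonormal")

    @property
    def n_residues(self) -> int:
        return self.n_res_a + self.n_res_b

    def to_json(self, path) -> None:
        d = asdict(self)
        d["sigma"] = np.asarray(self.sigma).tolist()
        for m in d["modes"]:
            m["vector"] = np.asarray(m["vector"]).tolist()
        for s in d["states"]:
            if s["displacement"] is not None:
                s["displacement"] = np.asarray(s["displacement"]).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["states"] = [
            PlantedState(
                intervals=[tuple(iv) for iv in s["intervals"]],
                displacement=None
                if s.get("displacement") is None
                else np.asarray(s["displacement"], dtype=float),
                separation=s.get("separation"),
            )
            for s in d.get("states", [])
        ]
        d["contacts"] = [PlantedContact(
            atom_a=tuple(c["atom_a"]), atom_b=tuple(c["atom_b"]), duty=c["duty"],
            bound=c.get("bound", 2.9), unbound=c.get("unbound", 12.0),
            schedule=c.get("schedule", "random"),
        ) for c in d.get("contacts", [])]
        d["modes"] = [PlantedMode(
            vector=np.asarray(m["vector"], dtype=float), amplitude=m["amplitude"],
            period=m["period"], phase=m.get("phase", 0.0),
        ) for m in d.get("modes", [])]
        sigma = d.get("sigma", 0.5)
        d["sigma"] = np.asarray(sigma, dtype=float) if isinstance(sigma, list) else sigma
        return cls(**d)


# ---------------------------------------------------------------------------
# reference geometry

_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.95, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.20, 0.95, 0.0]),
    "O": np.array([1.20, 2.18, 0.0]),
}


def build_reference(spec: SimSpec) -> Structure:
    """Idealized two-chain reference: straight chains along x, chain B offset
    by 30 A in y, consecutive CA atoms exactly 3.8 A apart."""
    atoms: list[AtomRecord] = []
    serial = 0
    for chain, n_res, y0 in (("A", spec.n_res_a, 0.0), ("B", spec.n_res_b, CHAIN_SEPARATION)):
        for r in range(n_res):
            base = np.array([CA_SPACING * r, y0, 0.0])
            names = ("CA",) if spec.backbone == "calpha_only" else ("N", "CA", "C", "O")
            for name in names:
                serial += 1
                pos = base + (_BACKBONE_OFFSETS[name] if spec.backbone == "full_backbone" else 0.0)
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        resname="ALA",
                        chain=chain,
                        resseq=r + 1,
                        coord=tuple(pos),
                        element="O" if name == "O" else ("N" if name == "N" else "C"),
                    )
                )
    struct = Structure(atoms, label="synthetic reference")
    coords = struct.coords
    a_idx = [i for i, at in enumerate(atoms) if at.chain == "A"]
    b_idx = [i for i, at in enumerate(atoms) if at.chain == "B"]
    gap = np.min(
        np.linalg.norm(coords[a_idx][:, None, :] - coords[b_idx][None, :, :], axis=2)
    )
    if gap < 4.0:
        raise GeometryError(f"chains overlap: minimum inter-chain distance {gap:.2f} A")
    return struct


def _residue_index_of_atoms(struct: Structure) -> np.ndarray:
    """Sequential residue index (0-based over the whole complex) per atom."""
    rid_order: dict[tuple[str, int], int] = {}
    for a in struct.atoms:
        rid_order.setdefault(a.residue_id, len(rid_order))
    return np.asarray([rid_order[a.residue_id] for a in struct.atoms], dtype=int)


def _zigzag_field(struct: Structure) -> np.ndarray:
    res_idx = _residue_index_of_atoms(struct)
    sign = np.where(res_idx % 2 == 0, 1.0, -1.0)
    field_ = np.zeros((len(struct), 3))
    field_[:, 2] = sign
    field_ -= field_.mean(axis=0)
    return field_


def _scaled_state_displacement(ref: np.ndarray, pattern: np.ndarray, separation: float) -> np.ndarray:
    """Scale a displacement pattern so the superposed RMSD from the reference
    equals ``separation`` (secant iteration; the response is near-linear)."""
    scale = separation / np.sqrt(np.mean(np.sum(pattern**2, axis=1)))
    for _ in range(20):
        r = kabsch(ref + scale * pattern, ref).rmsd
        if abs(r - separation) < 1e-9:
            break
        scale *= separation / r
    return scale * pattern


def _atom_sigma(spec: SimSpec, struct: Structure) -> np.ndarray:
    res_idx = _residue_index_of_atoms(struct)
    sigma = np.asarray(spec.sigma, dtype=float)
    if sigma.ndim == 0:
        return np.full(len(struct), float(sigma))
    if sigma.shape != (spec.n_residues,):
        raise SimSpecError(f"sigma must be scalar or length {spec.n_residues}")
    return sigma[res_idx]


def _noise_rng(spec: SimSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 0])


def _schedule_rng(spec: SimSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1])


def contact_schedules(spec: SimSpec) -> list[np.ndarray]:
    """Boolean bound/unbound schedule per planted contact, reproducible from
    the spec's seed alone."""
    rng = _schedule_rng(spec)
    n = spec.n_snapshots
    out = []
    for c in spec.contacts:
        if c.schedule == "random":
            out.append(rng.random(n) < c.duty)
        else:
            k = int(round(c.duty * n))
            sched = np.zeros(n, dtype=bool)
            sched[:k] = True
            out.append(sched)
    return out


def state_labels(spec: SimSpec) -> np.ndarray:
    """Per-snapshot state label: 0 = reference, i = spec.states[i-1]."""
    labels = np.zeros(spec.n_snapshots, dtype=int)
    for si, st in enumerate(spec.states, start=1):
        for a, b in st.intervals:
            if np.any(labels[a:b] != 0):
                raise SimSpecError("state intervals overlap")
            labels[a:b] = si
    return labels


def simulate(spec: SimSpec) -> Trajectory:
    """Generate the trajectory: reference + state displacement + modes +
    seeded Gaussian noise, with contact atoms repositioned per schedule."""
    ref_struct = build_reference(spec)
    ref = ref_struct.coords
    n_atoms = len(ref_struct)
    labels = state_labels(spec)

    disp_fields = [np.zeros((n_atoms, 3))]
    for st in spec.states:
        if st.displacement is not None:
            d = np.asarray(st.displacement, dtype=float)
            if d.shape != (n_atoms, 3):
                raise SimSpecError(f"state displacement must be ({n_atoms}, 3)")
        elif st.separation is not None:
            d = _scaled_state_displacement(ref, _zigzag_field(ref_struct), st.separation)
        else:
            raise SimSpecError("state needs a displacement or a separation")
        disp_fields.append(d)

    for m in spec.modes:
        if np.asarray(m.vector).shape != (3 * n_atoms,):
            raise SimSpecError(f"mode vectors must have length {3 * n_atoms}")

    sigma = _atom_sigma(spec, ref_struct)[:, None]
    rng = _noise_rng(spec)
    n = spec.n_snapshots
    frames = np.empty((n, n_atoms, 3))
    t = np.arange(n)
    mode_disp = np.zeros((n, n_atoms, 3))
    for m in spec.modes:
        score = m.amplitude * np.sin(2 * np.pi * t / m.period + m.phase)
        mode_disp += score[:, None, None] * np.asarray(m.vector).reshape(1, n_atoms, 3)

    noise_prev = np.zeros((n_atoms, 3))
    for fi in range(n):
        eps = rng.normal(0.0, 1.0, size=(n_atoms, 3))
        if spec.ar1 > 0 and fi > 0:
            noise = spec.ar1 * noise_prev + np.sqrt(1 - spec.ar1**2) * eps
        else:
            noise = eps
        noise_prev = noise
        frames[fi] = ref + disp_fields[labels[fi]] + mode_disp[fi] + sigma * noise

    # contact atoms overwritten last so planted distances are exact
    if spec.contacts:
        index = ref_struct.atom_index()
        schedules = contact_schedules(spec)
        for c, sched in zip(spec.contacts, schedules):
            ka = (c.atom_a[0], c.atom_a[1], "", c.atom_a[2])
            kb = (c.atom_b[0], c.atom_b[1], "", c.atom_b[2])
            for k, nm in ((ka, c.atom_a), (kb, c.atom_b)):
                if k not in index:
                    raise SimSpecError(f"contact atom {nm} not in reference")
            ia, ib = index[ka], index[kb]
            u = ref[ib] - ref[ia]
            u = u / np.linalg.norm(u)
            dist = np.where(sched, c.bound, c.unbound)
            frames[:, ib, :] = frames[:, ia, :] + dist[:, None] * u

    return Trajectory(
        topology=ref_struct.with_coords(frames[0]),
        frames=frames,
        dt_ns=spec.dt_ns,
    )


def ground_truth(spec: SimSpec) -> dict:
    """Machine-readable planted truth for the test suite.

    Keys: ``state_labels`` (per snapshot), ``rmsf`` (per residue, from the
    noise and mode variances: sqrt(3 sigma^2 + sum_m A_m^2 |v_m,r|^2 / 2),
    valid for specs without state displacements), ``contacts`` (expected =
    duty, realized = scheduled fraction), ``mode_vectors`` and
    ``mode_eigenvalues`` (A^2/2 per mode).
    """
    ref_struct = build_reference(spec)
    res_idx = _residue_index_of_atoms(ref_struct)
    sigma = np.asarray(spec.sigma, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(spec.n_residues, float(sigma))

    mode_var = np.zeros(spec.n_residues)
    ca_atoms = [i for i, a in enumerate(ref_struct.atoms) if a.name == "CA"]
    for m in spec.modes:
        v = np.asarray(m.vector).reshape(-1, 3)
        per_atom = np.sum(v**2, axis=1) * m.amplitude**2 / 2.0
        for i in ca_atoms:
            mode_var[res_idx[i]] += per_atom[i]

    schedules = contact_schedules(spec)
    contacts = [
        {
            "atom_a": c.atom_a,
            "atom_b": c.atom_b,
            "expected_fraction": c.duty,
            "realized_fraction": float(np.mean(s)),
            "schedule": s,
        }
        for c, s in zip(spec.contacts, schedules)
    ]
    residues = [
        (a.chain, a.resseq) for i, a in enumerate(ref_struct.atoms) if a.name == "CA"
    ]
    return {
        "state_labels": state_labels(spec),
        "residues": residues,
        "rmsf": np.sqrt(3.0 * sigma**2 + mode_var),
        "contacts": contacts,
        "mode_vectors": [np.asarray(m.vector, dtype=float) for m in spec.modes],
        "mode_eigenvalues": np.asarray([m.amplitude**2 / 2.0 for m in spec.modes]),
    }


def localized_mode(
    struct: Structure,
    components: dict[tuple[str, int], tuple[float, float, float]],
) -> np.ndarray:
    """Unit 3N vector moving the CA atoms of selected residues.

    ``components`` maps (chain, resseq) to an (unnormalized) 3-vector; all
    other atoms have zero weight. Useful for planting localized or
    anti-phase collective motions.
    """
    v = np.zeros((len(struct), 3))
    index = {(a.chain, a.resseq): i for i, a in enumerate(struct.atoms) if a.name == "CA"}
    for rid, comp in components.items():
        if rid not in index:
            raise KeyError(f"no CA atom for residue {rid}")
        v[index[rid]] = comp
    flat = v.ravel()
    norm = np.linalg.norm(flat)
    if norm == 0:
        raise ValueError("mode has no components")
    return flat / norm


def _rigid_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of infinitesimal rigid motions: three
    translations and three rotations about the centroid."""
    n = coords.shape[0]
    rel = coords - coords.mean(axis=0)
    basis = []
    for ax in np.eye(3):
        t = np.tile(ax, (n, 1))
        basis.append(t.ravel())
        basis.append(np.cross(np.tile(ax, (n, 1)), rel).ravel())
    B = np.stack(basis, axis=1)
    Q, _ = np.linalg.qr(B)
    return Q


def rigid_free_modes(struct: Structure, raw_vectors) -> list[np.ndarray]:
    """Project raw 3N vectors off the rigid-body subspace and orthonormalize.

    Superposition removes translation and rotation from every snapshot, so a
    planted mode with a rigid component would be partially absorbed by the
    alignment and recovered with a reduced eigenvalue and a tilted
    eigenvector. Planting only the rigid-free parts keeps the essential
    dynamics of the generated trajectory exactly the requested modes.
    """
    Q = _rigid_basis(struct.coords)
    out: list[np.ndarray] = []
    for v in raw_vectors:
        v = np.asarray(v, dtype=float).copy()
        v -= Q @ (Q.T @ v)
        for u in out:
            v -= u * (u @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ValueError("vector lies entirely in the rigid-body subspace")
        out.append(v / norm)
    return out


# ---------------------------------------------------------------------------
# internal-coordinate peptide builder (for dihedral oracles)

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.5


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from A, B, C internal
    coordinates: |CD| = bond, angle BCD, dihedral ABCD."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    n_res: int,
    phi: float,
    psi: float,
    omega: float = 180.0,
    chain: str = "A",
    resname: str = "ALA",
) -> Structure:
    """Backbone-only peptide with uniform (phi, psi, omega) dihedrals.

    Built residue by residue from canonical bond lengths and angles, so the
    dihedrals measured from the coordinates recover the inputs. phi = -57,
    psi = -47 gives the canonical alpha-helix.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(0, "N")] = np.zeros(3)
    coords[(0, "CA")] = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(_ANG_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + _BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(1, n_res):
        coords[(i, "N")] = _place(
            coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
            _BOND_C_N, _ANG_CA_C_N, psi,
        )
        coords[(i, "CA")] = _place(
            coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
            _BOND_N_CA, _ANG_C_N_CA, omega,
        )
        coords[(i, "C")] = _place(
            coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
            _BOND_CA_C, _ANG_N_CA_C, phi,
        )
    for i in range(n_res):
        coords[(i, "O")] = _place(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _BOND_C_O, _ANG_CA_C_O, psi + 180.0,
        )
    atoms = []
    serial = 0
    for i in range(n_res):
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    resname=resname,
                    chain=chain,
                    resseq=i + 1,
                    coord=tuple(coords[(i, name)]),
                    element="O" if name == "O" else ("N" if name == "N" else "C"),
                )
            )
    return Structure(atoms, label=f"ideal peptide phi={phi} psi={psi}")
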