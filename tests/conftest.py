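import pytest

from complexdyn import (
    AtomRecord,
    PlantedContact,
    PlantedMode,
    PlantedState,
    SimSpec,
    Structure,
    build_reference,
    localized_mode,
    rigid_free_modes,
    simulate,
)


def make_structure(spec_atoms, label="test"):
    """Build a Structure from (name, resname, chain, resseq, xyz) tuples."""
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=name,
            resname=resname,
            chain=chain,
            resseq=resseq,
            coord=tuple(xyz),
            element=name[0],
        )
        for i, (name, resname, chain, resseq, xyz) in enumerate(spec_atoms)
    ]
    return Structure(atoms, label=label)


@pytest.fixture
def two_state_spec():
    """Two planted conformational states, 5 A apart, 60/40 dwell split with
    the boundary on a coarse-frame edge; 1001 snapshots at 2 ns."""
    return SimSpec(
        n_res_a=30,
        n_res_b=20,
        n_snapshots=1001,
        dt_ns=2.0,
        sigma=0.3,
        states=[PlantedState(intervals=[(600, 1001)], separation=5.0)],
        seed=7,
    )


@pytest.fixture
def two_state_traj(two_state_spec):
    return simulate(two_state_spec)


@pytest.fixture
def quiet_spec():
    """Pure-noise complex: no states, contacts or modes."""
    return SimSpec(n_res_a=20, n_res_b=15, n_snapshots=200, sigma=0.4, seed=21)


@pytest.fixture
def quiet_traj(quiet_spec):
    return simulate(quiet_spec)


@pytest.fixture
def duty_cycle_spec():
    """Planted inter-chain hydrogen-bond contacts at four duty cycles."""
    return SimSpec(
        n_res_a=40,
        n_res_b=30,
        backbone="full_backbone",
        n_snapshots=2000,
        dt_ns=2.0,
        sigma=0.2,
        contacts=[
            PlantedContact(("A", 5, "O"), ("B", 5, "N"), duty=0.002),
            PlantedContact(("A", 15, "O"), ("B", 15, "N"), duty=0.02),
            PlantedContact(("A", 25, "O"), ("B", 25, "N"), duty=0.2),
            PlantedContact(("A", 35, "O"), ("B", 28, "N"), duty=0.8, schedule="block"),
        ],
        seed=5,
    )


@pytest.fixture
def mode_spec():
    """Two planted collective modes with a 4:1 eigenvalue ratio (amplitudes
    4 and 2 A), rigid-free so superposition does not absorb them."""
    base = SimSpec(n_res_a=40, n_res_b=30)
    ref = build_reference(base)
    raw1 = localized_mode(ref, {("B", r): (1, 0, 0) for r in range(5, 15)})
    raw2 = localized_mode(ref, {("A", r): (0, 0, 1) for r in range(10, 20)})
    v1, v2 = rigid_free_modes(ref, [raw1, raw2])
    return SimSpec(
        n_res_a=40,
        n_res_b=30,
        n_snapshots=2000,
        sigma=0.1,
        modes=[
            PlantedMode(v1, amplitude=4.0, period=40),
            PlantedMode(v2, amplitude=2.0, period=50, phase=0.7),
        ],
        seed=9,
    )
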