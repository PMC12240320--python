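import numpy as np
import pytest

from complexdyn import (
    ContactCriteria,
    Trajectory,
    distance_series,
    ground_truth,
    hydrogen_bonds,
    interface_residues,
    persistence,
    salt_bridges,
    simulate,
    tier_for_fraction,
)
from complexdyn.errors import HydrogenModeError, SelectionError
from conftest import make_structure


def ser_glu_pair(d, with_h=False, chain_b="B"):
    """SER OG (chain A) facing GLU OE1 (chain B) at distance d along x."""
    atoms = [
        ("N", "SER", "A", 1, (-3.0, 1.0, 0)),
        ("CA", "SER", "A", 1, (-2.0, 0.5, 0)),
        ("C", "SER", "A", 1, (-2.5, -1.0, 0)),
        ("O", "SER", "A", 1, (-3.5, -1.5, 0)),
        ("OG", "SER", "A", 1, (0.0, 0.0, 0.0)),
        ("N", "GLU", chain_b, 2, (d + 3.0, 1.0, 0)),
        ("CA", "GLU", chain_b, 2, (d + 2.0, 0.5, 0)),
        ("C", "GLU", chain_b, 2, (d + 2.5, -1.0, 0)),
        ("O", "GLU", chain_b, 2, (d + 3.5, -1.5, 0)),
        ("OE1", "GLU", chain_b, 2, (d, 0.0, 0.0)),
    ]
    if with_h:
        atoms.append(("HG", "SER", "A", 1, (0.97, 0.0, 0.0)))  # on the O-O axis
    s = make_structure(atoms)
    return s


class TestHydrogenBonds:
    def test_heavy_only_detects_within_cutoff(self):
        s = ser_glu_pair(2.8)
        pairs = hydrogen_bonds(s, ContactCriteria(hydrogen_mode="heavy_only"),
                               partition=({"A"}, {"B"}))
        assert any(d.name == "OG" and a.name == "OE1" for d, a in pairs)

    def test_distance_fail_absent(self):
        s = ser_glu_pair(3.5)
        crit = ContactCriteria(hb_da_cutoff=3.0, hydrogen_mode="heavy_only")
        pairs = hydrogen_bonds(s, crit, partition=({"A"}, {"B"}))
        assert not any(d.name == "OG" for d, a in pairs)

    def test_explicit_mode_angle_criterion(self):
        s = ser_glu_pair(2.8, with_h=True)
        pairs = hydrogen_bonds(s, ContactCriteria(hydrogen_mode="explicit"),
                               partition=({"A"}, {"B"}))
        assert any(d.name == "OG" and a.name == "OE1" for d, a in pairs)

    def test_explicit_mode_rejects_bent_geometry(self):
        s = ser_glu_pair(2.8, with_h=True)
        # move the hydrogen off-axis: D-H...A deviates far from linear
        atoms = [a for a in s.atoms if a.name != "HG"]
        from complexdyn import AtomRecord
        atoms.append(AtomRecord(serial=99, name="HG", resname="SER", chain="A",
                                resseq=1, coord=(0.0, 0.97, 0.0), element="H"))
        s2 = make_structure([(a.name, a.resname, a.chain, a.resseq, a.coord) for a in atoms])
        pairs = hydrogen_bonds(s2, ContactCriteria(hydrogen_mode="explicit"),
                               partition=({"A"}, {"B"}))
        assert not any(d.name == "OG" for d, a in pairs)

    def test_explicit_mode_without_hydrogens_raises(self):
        s = ser_glu_pair(2.8)
        with pytest.raises(HydrogenModeError, match="heavy_only"):
            hydrogen_bonds(s, ContactCriteria(hydrogen_mode="explicit"))

    def test_intra_chain_pair_excluded_under_partition(self):
        s = ser_glu_pair(2.8, chain_b="A")  # same chain now
        pairs = hydrogen_bonds(s, ContactCriteria(hydrogen_mode="heavy_only"),
                               partition=({"A"}, {"B"}))
        assert pairs == []


class TestSaltBridges:
    def glu_arg(self, d):
        return make_structure(
            [
                ("CA", "GLU", "A", 1, (-3.0, 0, 0)),
                ("OE2", "GLU", "A", 1, (0.0, 0, 0)),
                ("CA", "ARG", "B", 2, (d + 3.0, 0, 0)),
                ("NH1", "ARG", "B", 2, (d, 0, 0)),
            ]
        )

    def test_within_printed_cutoff_detected(self):
        pairs = salt_bridges(self.glu_arg(3.1))
        assert [(o.name, n.name) for o, n in pairs] == [("OE2", "NH1")]

    def test_beyond_printed_cutoff_absent(self):
        assert salt_bridges(self.glu_arg(3.3)) == []

    def test_backbone_oxygen_never_counts(self):
        s = make_structure(
            [
                ("CA", "GLY", "A", 1, (-3.0, 0, 0)),
                ("O", "GLY", "A", 1, (0.0, 0, 0)),  # backbone O
                ("CA", "LYS", "B", 2, (5.0, 0, 0)),
                ("NZ", "LYS", "B", 2, (2.0, 0, 0)),
            ]
        )
        assert salt_bridges(s) == []

    def test_histidine_optional(self):
        s = make_structure(
            [
                ("CA", "ASP", "A", 1, (-3.0, 0, 0)),
                ("OD1", "ASP", "A", 1, (0.0, 0, 0)),
                ("CA", "HIS", "B", 2, (5.0, 0, 0)),
                ("NE2", "HIS", "B", 2, (2.5, 0, 0)),
            ]
        )
        assert salt_bridges(s) == []
        assert len(salt_bridges(s, ContactCriteria(include_his=True))) == 1


class TestInterfaceResidues:
    def pair_at(self, d):
        return make_structure(
            [
                ("CA", "ALA", "A", 1, (0.0, 0, 0)),
                ("CB", "ALA", "A", 1, (1.0, 0, 0)),
                ("CA", "ALA", "B", 1, (1.0 + d, 0, 0)),
            ]
        )

    def test_between_printed_cutoffs(self):
        s = self.pair_at(5.5)
        ra6, rb6 = interface_residues(s, {"A"}, {"B"}, 6.0)
        assert ra6 and rb6
        with_5 = interface_residues(s, {"A"}, {"B"}, 5.0)
        assert with_5 == ([], [])

    def test_nested_cutoffs(self, duty_cycle_spec):
        snap = simulate(duty_cycle_spec).snapshot(0)
        sets = {}
        for c in (4.0, 5.0, 6.0):
            ra, rb = interface_residues(snap, {"A"}, {"B"}, c)
            sets[c] = (set(ra), set(rb))
        assert sets[4.0][0] <= sets[5.0][0] <= sets[6.0][0]
        assert sets[4.0][1] <= sets[5.0][1] <= sets[6.0][1]

    def test_symmetric_reporting(self):
        s = self.pair_at(5.5)
        ra, rb = interface_residues(s, {"A"}, {"B"}, 6.0)
        assert bool(ra) == bool(rb)

    def test_unknown_chain_raises(self):
        with pytest.raises(SelectionError):
            interface_residues(self.pair_at(5.0), {"A"}, {"Z"}, 6.0)


class TestDistanceSeries:
    def test_static_pair_constant(self):
        s = make_structure(
            [("CA", "GLY", "A", 1, (0, 0, 0)), ("CA", "GLY", "B", 1, (4.0, 0, 0))]
        )
        t = Trajectory(topology=s, frames=np.repeat(s.coords[None], 4, axis=0), dt_ns=2.0)
        ds = distance_series(t, [("A", 1, "CA")], [("B", 1, "CA")])
        np.testing.assert_allclose(ds.values, 4.0)
        np.testing.assert_allclose(ds.times_ns, [0, 2, 4, 6])

    def test_sinusoidal_separation_reproduced(self):
        s = make_structure(
            [("CA", "GLY", "A", 1, (0, 0, 0)), ("CA", "GLY", "B", 1, (5.0, 0, 0))]
        )
        n = 50
        frames = np.repeat(s.coords[None], n, axis=0)
        sep = 5.0 + 2.0 * np.sin(2 * np.pi * np.arange(n) / 4)
        frames[:, 1, 0] = sep
        t = Trajectory(topology=s, frames=frames)
        ds = distance_series(t, [("A", 1, "CA")], [("B", 1, "CA")])
        np.testing.assert_allclose(ds.values, sep, atol=1e-6)
        assert ds.values.min() == pytest.approx(3.0, abs=1e-6)
        assert ds.values.max() == pytest.approx(7.0, abs=1e-6)

    def test_missing_atom_key_named(self, quiet_traj):
        with pytest.raises(KeyError, match="XX"):
            distance_series(quiet_traj, [("A", 1, "XX")], [("B", 1, "CA")])


class TestPersistence:
    def test_tier_edges_strict(self):
        assert tier_for_fraction(0.051) == "stable>=5%"
        assert tier_for_fraction(0.05) == ">=1%"
        assert tier_for_fraction(0.011) == ">=1%"
        assert tier_for_fraction(0.0011) == ">=0.1%"
        assert tier_for_fraction(0.001) == "below"

    def test_duration_matches_trajectory_length(self, duty_cycle_spec):
        traj = simulate(duty_cycle_spec)
        recs = persistence(traj, partition=({"A"}, {"B"}), kinds=("hbond",))
        total_ns = traj.n_frames * traj.dt_ns
        for r in recs:
            assert r.duration_ns == pytest.approx(r.fraction * total_ns)

    def test_planted_duty_cycles_recovered_with_tiers(self, duty_cycle_spec):
        """Duty cycles 0.002/0.02/0.2/0.8 recovered within 3 binomial SD and
        mapped to the expected occupancy tiers."""
        traj = simulate(duty_cycle_spec)
        recs = persistence(traj, partition=({"A"}, {"B"}), kinds=("hbond",))
        by_pair = {((r.res_a[0], r.res_a[1]), (r.res_b[0], r.res_b[1])): r for r in recs}
        truth = ground_truth(duty_cycle_spec)["contacts"]
        n = duty_cycle_spec.n_snapshots
        expected_tiers = [">=0.1%", ">=1%", "stable>=5%", "stable>=5%"]
        for t, tier in zip(truth, expected_tiers):
            key = (t["atom_a"][:2], t["atom_b"][:2])
            rec = by_pair[key]
            p = t["expected_fraction"]
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(rec.fraction - p) <= 3 * sd + 1e-12
            assert rec.fraction == pytest.approx(t["realized_fraction"], abs=1e-12)
            assert rec.tier == tier

    def test_never_formed_contact_absent(self, quiet_traj):
        # pure-noise chains stay ~30 A apart: no inter-chain contacts at all
        recs = persistence(quiet_traj, partition=({"A"}, {"B"}))
        assert recs == []
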