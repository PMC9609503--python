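import io

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ramagg as rg
from ramagg.exceptions import (
    CongruenceError,
    EmptyStructureError,
    LookupError_,
    StructureParseError,
)
from ramagg.peptides import build_model
from ramagg.structure import (
    Atom,
    Chain,
    InteractionCriteria,
    Residue,
    StructureModel,
    Trajectory,
    backbone_rmsd,
    com_distance,
    cys_pair_distances,
    detect_interactions,
    read_structure,
    write_structure,
)
from ramagg.synthetic import ContactSpec

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


def two_model_pdb():
    buf = io.StringIO()
    model = build_model(["ALA"] * 4, -57.0, -47.0)
    traj = Trajectory(model, np.stack([model.coords(), model.coords() + 1.0]))
    write_structure(traj, buf)
    return buf.getvalue()


class TestReadStructure:
    def test_toy_pdb_parses_to_one_chain_one_residue_three_atoms(self):
        m = read_structure(TOY_PDB)
        assert len(m.chains) == 1
        assert len(m.chains[0].residues) == 1
        assert len(m.chains[0].residues[0].atoms) == 3

    def test_two_model_file_becomes_trajectory(self):
        t = read_structure(two_model_pdb())
        assert isinstance(t, Trajectory)
        assert t.n_frames == 2

    def test_write_read_round_trip_at_pdb_precision(self):
        dimer = rg.hewl_like_dimer()
        buf = io.StringIO()
        write_structure(dimer, buf)
        back = read_structure(buf.getvalue())
        assert back.n_atoms == dimer.n_atoms
        assert np.max(np.abs(back.coords() - dimer.coords())) < 1e-3

    def test_malformed_coordinates_report_line_number(self):
        bad = TOY_PDB.replace("       1.458", "        abcd")
        with pytest.raises(StructureParseError) as err:
            read_structure(bad)
        assert err.value.line == 2

    def test_truncated_atom_record_rejected(self):
        with pytest.raises(StructureParseError):
            read_structure("ATOM      1  N   ALA A   1       0.000\n")

    def test_no_atoms_is_an_empty_structure_error(self):
        with pytest.raises(EmptyStructureError):
            read_structure("HEADER    NOTHING\nEND\n")

    def test_element_inferred_from_atom_name_when_column_absent(self):
        no_element = "\n".join(line[:66] for line in TOY_PDB.splitlines()) + "\n"
        m = read_structure(no_element)
        assert [a.element for a in m.chains[0].residues[0].atoms] == ["N", "C", "C"]


from conftest import rotation_grid_rmsd as brute_force_rmsd  # noqa: E402


class TestBackboneRmsd:
    def test_identity_is_zero(self):
        m = build_model(["ALA"] * 6, -57.0, -47.0)
        assert backbone_rmsd(m, m) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transform_invariance(self):
        m = build_model(["ALA"] * 6, -57.0, -47.0)
        rot = Rotation.from_euler("xyz", [np.pi / 2, 0.4, -1.2]).as_matrix()
        moved = m.with_coords(m.coords() @ rot.T + np.array([3.0, -7.0, 11.0]))
        assert backbone_rmsd(moved, m) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_in_arguments(self):
        a = build_model(["ALA"] * 6, -57.0, -47.0)
        b = build_model(["ALA"] * 6, -120.0, 130.0)
        assert backbone_rmsd(a, b) == pytest.approx(backbone_rmsd(b, a), abs=1e-9)

    def test_matches_brute_force_rotation_grid_on_four_atom_toy(self):
        ref = np.array([
            [0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 3.0, 0.0], [0.0, 0.0, 4.0],
        ])
        frame = ref.copy()
        frame[3] += np.array([0.0, 0.0, 2.0])  # one atom displaced 2 A along z

        def as_model(coords):
            atoms = [Atom(n, "C", p) for n, p in zip(("N", "CA", "C", "O"), coords)]
            return StructureModel([Chain("A", [Residue(1, "ALA", atoms)])])

        exact = backbone_rmsd(as_model(frame), as_model(ref))
        grid = brute_force_rmsd(frame, ref)
        assert exact <= grid + 1e-9  # the oracle cannot beat the optimum
        assert exact == pytest.approx(grid, abs=1e-3)

    def test_mismatched_selections_rejected(self):
        a = build_model(["ALA"] * 6, -57.0, -47.0)
        b = build_model(["ALA"] * 5, -57.0, -47.0)
        with pytest.raises(CongruenceError):
            backbone_rmsd(a, b)


class TestComDistance:
    def make_two_point_model(self, mass_b=12.011):
        a = Chain("A", [Residue(1, "ALA", [Atom("CA", "C", np.zeros(3))])])
        b = Chain("B", [Residue(1, "ALA", [Atom("CA", "C", np.array([0.0, 0.0, 10.0]),
                                                mass=mass_b)])])
        return StructureModel([a, b])

    def test_two_single_atom_chains(self):
        assert com_distance(self.make_two_point_model(), "A", "B") == pytest.approx(10.0)

    def test_equal_masses_make_weighting_irrelevant(self):
        m = self.make_two_point_model()
        d1 = com_distance(m, "A", "B", mass_weighted=True)
        d2 = com_distance(m, "A", "B", mass_weighted=False)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_first_frame_of_neutral_approach_course(self):
        traj = rg.generate_dimer_trajectory(n_frames=4, com_start=33.78, com_end=30.0)
        assert com_distance(traj.frame(0), "A", "B") == pytest.approx(33.78, abs=1e-6)

    def test_missing_chain_is_a_lookup_error(self):
        with pytest.raises(LookupError_):
            com_distance(self.make_two_point_model(), "A", "Z")


class TestCysPairDistances:
    def test_superposed_identical_chains_have_zero_diagonal(self):
        a = rg.hewl_like_dimer(separation=30.0)
        chain_a = a.chain("A")
        import copy

        superposed = StructureModel([
            chain_a,
            Chain("B", copy.deepcopy(chain_a.residues)),
        ])
        ia, ib, d = cys_pair_distances(superposed)
        assert np.allclose(np.diag(d), 0.0)

    def test_planted_closest_pair_identified(self):
        dimer = rg.hewl_like_dimer(separation=30.0)
        sg_a = next(r for r in dimer.chain("A").residues if r.index == 30).atom("SG")
        sg_b = next(r for r in dimer.chain("B").residues if r.index == 115).atom("SG")
        sg_a.pos = np.array([5.0, 5.0, 13.0])
        sg_b.pos = np.array([5.0, 5.0, 17.0])  # planted closest pair at 4.0 A
        ra, rb, dmin = rg.min_cys_pair(dimer)
        assert (ra, rb) == (30, 115)
        assert dmin == pytest.approx(4.0, abs=1e-3)

    def test_chain_without_cysteines_warns_and_returns_empty(self):
        m = build_model(["ALA"] * 6, -120.0, 130.0)
        dimer = StructureModel([m.chains[0], Chain("B", rg.hewl_like_chain("B").residues)])
        with pytest.warns(UserWarning):
            _, _, d = cys_pair_distances(dimer)
        assert d.size == 0


class TestAssignSecondaryStructure:
    def test_canonical_helix_is_alpha(self):
        labels, content = rg.assign_secondary_structure(build_model(["ALA"] * 20, -57.0, -47.0))
        assert content["alpha"] >= 95.0

    def test_canonical_strand_is_beta(self):
        _, content = rg.assign_secondary_structure(build_model(["ALA"] * 20, -120.0, 130.0))
        assert content["beta"] >= 95.0

    def test_mixed_chain_matches_construction_within_5pp(self):
        n_a, n_b = 14, 10
        phi = [-57.0] * n_a + [-120.0] * n_b
        psi = [-47.0] * n_a + [130.0] * n_b
        _, content = rg.assign_secondary_structure(build_model(["ALA"] * (n_a + n_b), phi, psi))
        assignable = n_a + n_b - 2  # chain termini lack phi or psi
        assert content["alpha"] == pytest.approx(100.0 * (n_a - 1) / assignable, abs=5.0)
        assert content["beta"] == pytest.approx(100.0 * (n_b - 1) / assignable, abs=5.0)

    def test_short_runs_demoted_to_other(self):
        phi = [-120.0] * 8 + [-57.0] * 2 + [-120.0] * 8
        psi = [130.0] * 8 + [-47.0] * 2 + [130.0] * 8
        labels, _ = rg.assign_secondary_structure(build_model(["ALA"] * 18, phi, psi))
        by_index = {idx: lab for _, idx, lab in labels}
        assert by_index[9] == "other" and by_index[10] == "other"

    def test_percentages_sum_to_100(self):
        _, content = rg.assign_secondary_structure(build_model(["ALA"] * 15, -57.0, -47.0))
        assert sum(content.values()) == pytest.approx(100.0, abs=1e-9)


class TestDetectInteractions:
    def pair_model(self, distance):
        # donor: SER OG on chain A; acceptor: backbone O on chain B (chain B
        # has no donors, so the contact is strictly A -> B)
        a = Chain("A", [Residue(1, "SER", [
            Atom("CA", "C", np.zeros(3)), Atom("OG", "O", np.array([0.0, 0.0, 1.0]))])])
        b = Chain("B", [Residue(1, "ALA", [
            Atom("CA", "C", np.array([0.0, 0.0, 2.0 + distance])),
            Atom("O", "O", np.array([0.0, 0.0, 1.0 + distance]))])])
        return StructureModel([a, b])

    def test_close_donor_acceptor_pair_is_one_hydrogen_bond(self):
        _, counts = detect_interactions(self.pair_model(2.9))
        assert counts["hydrogen_bond"] == 1

    def test_distant_pair_is_no_hydrogen_bond(self):
        _, counts = detect_interactions(self.pair_model(5.0))
        assert counts["hydrogen_bond"] == 0

    def test_donor_angle_gate_applies_when_hydrogen_present(self):
        m = self.pair_model(2.9)
        # hydrogen placed so the D-H...A angle is ~0 deg: geometry must fail
        m.chains[0].residues[0].atoms.append(
            Atom("HG", "H", np.array([0.0, 0.0, 0.0]))
        )
        _, counts = detect_interactions(m)
        assert counts["hydrogen_bond"] == 0

    def test_planted_mixed_contacts_counted_exactly(self):
        traj = rg.generate_dimer_trajectory(
            n_frames=3, com_start=27.19, com_end=23.0,
            planted_contacts=[
                ContactSpec("salt_bridge", 4, 4),
                ContactSpec("salt_bridge", 9, 9),
                ContactSpec("salt_bridge", 14, 14),
                ContactSpec("hydrogen_bond", 19, 19),
                ContactSpec("hydrogen_bond", 23, 23),
            ],
        )
        _, counts = detect_interactions(traj.frame(2))
        assert counts["salt_bridge"] == 3
        assert counts["hydrogen_bond"] == 2
        assert counts["pi_cation"] == 0 and counts["pi_pi"] == 0

    def test_counts_invariant_under_global_rotation(self):
        traj = rg.generate_dimer_trajectory(
            n_frames=2, com_start=27.19, com_end=23.0,
            planted_contacts=[ContactSpec("salt_bridge", 6, 6),
                              ContactSpec("pi_pi", 14, 14)],
        )
        frame = traj.frame(1)
        _, counts = detect_interactions(frame)
        rot = Rotation.from_euler("xyz", [0.7, -1.1, 2.3]).as_matrix()
        moved = frame.with_coords(frame.coords() @ rot.T + np.array([12.0, -5.0, 9.0]))
        _, counts_rot = detect_interactions(moved)
        assert counts == counts_rot

    def test_his_cation_only_when_flagged(self):
        a = Chain("A", [Residue(1, "HIS", [
            Atom("CA", "C", np.zeros(3)),
            Atom("ND1", "N", np.array([0.0, 0.0, 1.0])),
            Atom("CG", "C", np.array([0.4, 0.0, 0.6])),
            Atom("CD2", "C", np.array([0.8, 0.4, 0.9])),
            Atom("CE1", "N", np.array([0.1, 0.6, 1.4])),
            Atom("NE2", "N", np.array([0.6, 0.8, 1.3]))])])
        b = Chain("B", [Residue(1, "ASP", [
            Atom("CA", "C", np.array([0.0, 0.0, 6.0])),
            Atom("OD1", "O", np.array([0.0, 0.0, 4.5]))])])
        m = StructureModel([a, b])
        _, default_counts = detect_interactions(m)
        _, charged_counts = detect_interactions(
            m, criteria=InteractionCriteria(his_charged=True))
        assert default_counts["salt_bridge"] == 0
        assert charged_counts["salt_bridge"] == 1
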