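import numpy as np
import pytest

from protdyn.residues import SIDECHAIN_ICOORDS, ONE_TO_THREE
from protdyn.structure import (EmptyStructureError, MutationError,
                               MutationSpec, PDBFormatError, build_mutant,
                               extract_coarse_grain, make_toy_structure,
                               read_structure, write_mode_trajectory,
                               write_structure, TooFewSitesError)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       2.400   2.000   3.000  1.00 10.00           C
ATOM      3  C   ALA A   1       3.100   3.300   3.000  1.00 10.00           C
ATOM      4  O   ALA A   1       2.500   4.400   3.000  1.00 10.00           O
ATOM      5  N   GLY A   2       4.400   3.300   3.000  1.00 10.00           N
ATOM      6  CA  GLY A   2       5.200   4.500   3.000  1.00 10.00           C
ATOM      7  C   GLY A   2       6.700   4.300   3.000  1.00 10.00           C
ATOM      8  O   GLY A   2       7.300   3.200   3.000  1.00 10.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA AALA A   1       1.400   0.000   0.000  0.60 10.00           C
ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.40 10.00           C
ATOM      4  C   ALA A   1       2.100   1.300   0.000  1.00 10.00           C
ATOM      5  N   GLY A   2       3.400   1.300   0.000  1.00 10.00           N
ATOM      6  CA  GLY A   2       4.200   2.500   0.000  1.00 10.00           C
ATOM      7  C   GLY A   2       5.700   2.300   0.000  1.00 10.00           C
END
"""


class TestReadStructure:
    def test_identity_parse(self):
        s = read_structure(MINIMAL_PDB)
        residues = s.residues()
        assert [r.name for r in residues] == ["ALA", "GLY"]
        np.testing.assert_allclose(residues[0].atom("N").coords, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(residues[1].atom("CA").coords, [5.2, 4.5, 3.0])
        assert s.sequence("A") == "AG"

    def test_altloc_highest_occupancy_wins(self):
        s = read_structure(ALTLOC_PDB)
        ca = s.get_residue("A", 1).atom("CA")
        assert ca.occupancy == pytest.approx(0.6)
        np.testing.assert_allclose(ca.coords, [1.4, 0.0, 0.0])

    def test_altloc_tie_breaks_alphabetically(self):
        tied = ALTLOC_PDB.replace("0.60", "0.50").replace("0.40", "0.50")
        ca = read_structure(tied).get_residue("A", 1).atom("CA")
        assert ca.altloc == "A"

    def test_hetatm_separated_from_protein(self):
        pdb = MINIMAL_PDB.replace(
            "END",
            "HETATM    9  O   HOH A 100      9.000   9.000   9.000  1.00  0.00           O\nEND",
        )
        s = read_structure(pdb)
        assert len(s.atoms) == 8
        assert len(s.het_atoms) == 1

    def test_empty_structure_error(self):
        with pytest.raises((EmptyStructureError, PDBFormatError)):
            read_structure("HETATM    1  O   HOH A   1       0.0     0.0     0.0\nEND\n")

    def test_missing_file_error(self):
        with pytest.raises(PDBFormatError):
            read_structure("/nonexistent/file.pdb")


def test_write_read_round_trip(tmp_path, helix20):
    path = tmp_path / "helix.pdb"
    write_structure(helix20, path)
    again = read_structure(path)
    assert len(again.atoms) == len(helix20.atoms)
    np.testing.assert_allclose(again.coords_array(), helix20.coords_array(),
                               atol=1e-3)
    orig = [(a.chain_id, a.residue_number, a.residue_name, a.name)
            for a in helix20.atoms]
    back = [(a.chain_id, a.residue_number, a.residue_name, a.name)
            for a in again.atoms]
    assert orig == back


class TestCoarseGrain:
    def test_one_site_per_residue(self, helix20):
        cg = extract_coarse_grain(helix20)
        assert len(cg) == 20
        assert [s.residue_number for s in cg.sites] == list(range(1, 21))

    def test_missing_ca_skipped_and_reported(self, helix20):
        damaged = helix20.copy()
        damaged.atoms = [a for a in damaged.atoms
                         if not (a.residue_number == 5 and a.name == "CA")]
        cg = extract_coarse_grain(damaged)
        assert len(cg) == 19
        assert cg.skipped == [("A", 5, "")]

    def test_unit_mass_scheme(self, helix20):
        cg = extract_coarse_grain(helix20, mass_scheme="unit")
        assert np.all(cg.masses() == 1.0)

    def test_residue_masses_positive_and_typed(self, helix20):
        cg = extract_coarse_grain(helix20)
        assert np.all(cg.masses() > 0)
        assert cg.masses()[0] == pytest.approx(71.08)  # Ala

    def test_too_few_sites(self):
        s = read_structure(MINIMAL_PDB)
        s.atoms = [a for a in s.atoms if a.residue_number == 1]
        with pytest.raises(TooFewSitesError):
            extract_coarse_grain(s)


class TestBuildMutant:
    def test_truncation_to_ala(self, cluster30):
        spec = MutationSpec.parse("L3A", "A")
        mut = build_mutant(cluster30, spec)
        res = mut.get_residue("A", 3)
        assert res.name == "ALA"
        assert sorted(a.name for a in res.atoms) == ["C", "CA", "CB", "N", "O"]

    def test_backbone_never_moves(self, cluster30):
        for text in ("L3A", "V2W", "K4R", "D5G", "E6F"):
            spec = MutationSpec.parse(text, "A")
            mut = build_mutant(cluster30, spec)
            for name in ("N", "CA", "C", "O"):
                wt_atom = cluster30.get_residue("A", spec.residue_number).atom(name)
                mu_atom = mut.get_residue("A", spec.residue_number).atom(name)
                assert np.array_equal(wt_atom.coords, mu_atom.coords)
        # and all other residues are untouched
        spec = MutationSpec.parse("L3A", "A")
        mut = build_mutant(cluster30, spec)
        wt_other = [a.coords for a in cluster30.atoms if a.residue_number != 3]
        mu_other = [a.coords for a in mut.atoms if a.residue_number != 3]
        np.testing.assert_array_equal(np.array(wt_other), np.array(mu_other))

    def test_gly_to_ala_ideal_cb(self):
        s = make_toy_structure("ideal_helix", 5, sequence="GGGGG")
        mut = build_mutant(s, MutationSpec.parse("G3A", "A"))
        res = mut.get_residue("A", 3)
        d = np.linalg.norm(res.atom("CB").coords - res.atom("CA").coords)
        assert d == pytest.approx(1.53, abs=0.02)

    def test_wild_type_mismatch(self, cluster30):
        with pytest.raises(MutationError, match="VAL"):
            build_mutant(cluster30, MutationSpec.parse("A2G", "A"))

    def test_residue_not_found(self, cluster30):
        with pytest.raises(MutationError, match="not found"):
            build_mutant(cluster30, MutationSpec.parse("A99G", "A"))

    @pytest.mark.parametrize("target", sorted(ONE_TO_THREE))
    def test_all_targets_have_complete_sidechains(self, cluster30, target):
        if target == "L":
            return
        spec = MutationSpec(chain_id="A", wild_aa="L", residue_number=3,
                            mutant_aa=target)
        res = build_mutant(cluster30, spec).get_residue("A", 3)
        expected = {"N", "CA", "C", "O"}
        expected |= {name for name, *_ in SIDECHAIN_ICOORDS[ONE_TO_THREE[target]]}
        assert {a.name for a in res.atoms} == expected


class TestMutationSpec:
    def test_parse_simple(self):
        spec = MutationSpec.parse("A17G", "B")
        assert (spec.wild_aa, spec.residue_number, spec.mutant_aa,
                spec.chain_id) == ("A", 17, "G", "B")

    def test_parse_insertion_code(self):
        spec = MutationSpec.parse("A17aG", "A")
        assert spec.insertion_code == "a"
        assert spec.residue_number == 17

    def test_reverse_round_trips(self):
        spec = MutationSpec.parse("A17G", "A")
        assert spec.reverse().reverse() == spec

    def test_nonstandard_code_rejected(self):
        with pytest.raises(MutationError):
            MutationSpec.parse("A17X", "A")


class TestModeTrajectory:
    def test_zero_mode_gives_identical_frames(self, tmp_path, helix20_cg):
        path = tmp_path / "traj.pdb"
        write_mode_trajectory(helix20_cg, np.zeros((20, 3)), amplitude=2.0,
                              n_frames=4, path=path)
        frames = [read_structure(str(path), model=k) for k in range(1, 5)]
        for f in frames[1:]:
            np.testing.assert_allclose(f.coords_array(),
                                       frames[0].coords_array(), atol=1e-3)

    def test_phase_pi_frame_matches_input(self, tmp_path, helix20_cg):
        mode = np.zeros((20, 3))
        mode[0] = [1.0, 0.0, 0.0]
        path = tmp_path / "traj.pdb"
        write_mode_trajectory(helix20_cg, mode, amplitude=2.0, n_frames=4,
                              path=path)
        # frame k=2 of 4 has phase sin(pi) = 0
        frame2 = read_structure(str(path), model=2)
        np.testing.assert_allclose(frame2.coords_array(), helix20_cg.coords(),
                                   atol=1e-3)

    def test_max_excursion_equals_amplitude(self, tmp_path, helix20_cg):
        mode = np.zeros((20, 3))
        mode[3] = [1.0, 0.0, 0.0]
        path = tmp_path / "traj.pdb"
        write_mode_trajectory(helix20_cg, mode, amplitude=2.0, n_frames=8,
                              path=path)
        base_x = helix20_cg.coords()[3, 0]
        xs = [read_structure(str(path), model=k).coords_array()[3, 0]
              for k in range(1, 9)]
        assert max(abs(x - base_x) for x in xs) == pytest.approx(2.0, abs=1e-3)

    def test_dimension_mismatch(self, tmp_path, helix20_cg):
        with pytest.raises(ValueError):
            write_mode_trajectory(helix20_cg, np.zeros((7, 3)), 1.0, 4,
                                  tmp_path / "x.pdb")


class TestToyStructures:
    def test_helix_ca_spacing(self):
        s = make_toy_structure("ideal_helix", 10)
        d = np.linalg.norm(np.diff(extract_coarse_grain(s).coords(), axis=0),
                           axis=1)
        assert np.all(np.abs(d - 3.8) < 0.1)

    def test_seed_determinism(self):
        a = make_toy_structure("cluster", 30, seed=7)
        b = make_toy_structure("cluster", 30, seed=7)
        np.testing.assert_array_equal(a.coords_array(), b.coords_array())

    def test_cluster_radius_of_gyration(self):
        s = make_toy_structure("cluster", 30, seed=0)
        x = s.coords_array()
        rg = np.sqrt(np.mean(np.sum((x - x.mean(axis=0)) ** 2, axis=1)))
        assert np.isfinite(rg) and rg > 0

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_toy_structure("spiral", 10)

    def test_too_short(self):
        with pytest.raises(ValueError):
            make_toy_structure("ideal_helix", 1)
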