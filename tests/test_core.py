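import numpy as np
import pytest

from trajsite.core import (
    Atom,
    EmptyStructureError,
    ParseError,
    RegionSpec,
    Topology,
    Trajectory,
    assign_regions,
    infer_element,
    read_structure,
    read_trajectory,
    sample_frames,
    write_structure,
    write_trajectory,
)

from conftest import backbone_residue, make_topology

# the Uniprot-derived domain layout of a 7-TM receptor, used as a realistic
# RegionSpec fixture throughout
TM_RANGES = [(12, 32), (43, 63), (93, 113), (132, 152), (202, 222), (255, 275), (285, 305)]
EC_RANGES = [(1, 11), (64, 92), (153, 201), (276, 284)]


def seven_tm_spec():
    ranges = [("transmembrane", a, b) for a, b in TM_RANGES]
    ranges += [("extracellular", a, b) for a, b in EC_RANGES]
    return RegionSpec(ranges)


class TestAtom:
    def test_requires_element(self):
        with pytest.raises(ValueError):
            Atom(serial=1, name="CA", element="", residue_seq=1,
                 residue_name="ALA", chain="A")

    def test_requires_positive_residue_seq(self):
        with pytest.raises(ValueError):
            Atom(serial=1, name="CA", element="C", residue_seq=0,
                 residue_name="ALA", chain="A")


class TestTopology:
    def test_duplicate_atom_identity_rejected(self):
        atoms = [Atom(1, "CA", "C", 1, "ALA", "A"), Atom(2, "CA", "C", 1, "ALA", "A")]
        with pytest.raises(ValueError, match="duplicate"):
            Topology(atoms)

    def test_residue_classes(self):
        top = make_topology([
            (1, "ALA", [("CA", "C")]),
            (2, "HOH", [("O", "O")]),
            (3, "NA", [("NA", "Na")]),
            (4, "DKT", [("C1", "C")]),
        ])
        assert top.residue_class(("A", 1)) == "protein"
        assert top.residue_class(("A", 2)) == "water"
        assert top.residue_class(("A", 3)) == "ion"
        assert top.residue_class(("A", 4)) == "ligand"
        assert top.ligand_residues() == [("A", 4)]

    def test_ligand_override(self):
        atoms = [Atom(1, "CA", "C", 1, "ALA", "A")]
        top = Topology(atoms, ligand_names=["ALA"])
        assert top.residue_class(("A", 1)) == "ligand"

    def test_selections(self):
        top = make_topology([backbone_residue(1), backbone_residue(2),
                             (3, "ALA", [("CA", "C"), ("HA", "H")])])
        assert list(top.ca_indices()) == [1, 5, 8]
        assert top.backbone_indices().size == 9  # 4 + 4 + lone CA
        assert top.select(heavy=True).size == 9
        assert list(top.select(names={"CA"}, residues={("A", 2)})) == [5]


class TestReadStructure:
    def test_two_residue_fixture(self, two_residue_pdb):
        top, coords = read_structure(two_residue_pdb)
        assert top.n_residues == 2
        assert [a.name for a in top.atoms] == ["N", "CA", "C", "O"] * 2
        assert top.residues[0] == ("A", 1, "ALA")
        assert top.residues[1] == ("A", 2, "GLY")

    def test_angstrom_to_nm(self, two_residue_pdb):
        _, coords = read_structure(two_residue_pdb)
        assert coords[0, 0] == pytest.approx(1.0)  # 10.000 A -> 1.000 nm

    def test_water_only_file(self, water_only_pdb):
        top, coords = read_structure(water_only_pdb)
        assert top.protein_residues() == []
        assert all(top.residue_class(k) == "water" for k in top.residue_keys())

    def test_empty_structure(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyStructureError, match="empty structure"):
            read_structure(path)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1      10.000   0.000   0.000\n"
            "ATOM      2  CA  ALA A   1      xx.xxx   0.000   0.000\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_structure(path)

    def test_gro(self, tmp_path):
        path = tmp_path / "s.gro"
        path.write_text(
            "toy\n"
            "    2\n"
            "    1ALA      N    1   1.000   0.000   0.000\n"
            "    1ALA     CA    2   1.100   0.050   0.000\n"
            "   0.0 0.0 0.0\n"
        )
        top, coords = read_structure(path)
        assert top.n_atoms == 2
        assert coords[0, 0] == pytest.approx(1.0)  # GRO is already nm


class TestRoundTrip:
    def test_structure_roundtrip(self, tmp_path, rng):
        top = make_topology([backbone_residue(1, "ALA"), backbone_residue(2, "PHE")])
        coords = rng.uniform(-2, 2, size=(8, 3))
        path = tmp_path / "rt.pdb"
        write_structure(path, top, coords)
        top2, coords2 = read_structure(path)
        assert [a.name for a in top2.atoms] == [a.name for a in top.atoms]
        assert [a.residue_seq for a in top2.atoms] == [a.residue_seq for a in top.atoms]
        # PDB stores 0.001 A = 1e-4 nm precision
        np.testing.assert_allclose(coords2, coords, atol=1e-4)

    def test_trajectory_roundtrip_frames(self, tmp_path, rng):
        top = make_topology([backbone_residue(1)])
        coords = rng.uniform(-1, 1, size=(3, 4, 3))
        traj = Trajectory(top, coords, np.array([0.0, 0.5, 1.2]))
        path = tmp_path / "t.frames.txt"
        write_trajectory(path, traj)
        back = read_trajectory(path, top)
        np.testing.assert_allclose(back.coords, coords, atol=1e-6)
        np.testing.assert_allclose(back.times, traj.times)

    def test_trajectory_roundtrip_pdb(self, tmp_path, rng):
        top = make_topology([backbone_residue(1)])
        coords = rng.uniform(-1, 1, size=(2, 4, 3))
        traj = Trajectory(top, coords, np.array([0.0, 1.0]))
        path = tmp_path / "t.pdb"
        write_trajectory(path, traj, format="pdb")
        back = read_trajectory(path, top, start_ns=0.0, stride_ns=1.0)
        np.testing.assert_allclose(back.coords, coords, atol=1e-4)


class TestReadTrajectory:
    def _multi_model(self, tmp_path, n_models, drop_atom_in=None):
        blocks = []
        for m in range(1, n_models + 1):
            lines = [f"MODEL     {m}"]
            for i, (name, x) in enumerate([("N", 1.0), ("CA", 2.0), ("C", 3.0), ("O", 4.0)]):
                if drop_atom_in == m and name == "O":
                    continue
                lines.append(
                    f"ATOM  {i + 1:>5d}  {name:<3s}ALA A   1    "
                    f"{x + m:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           {name[0]}"
                )
            lines.append("ENDMDL")
            blocks.append("\n".join(lines))
        path = tmp_path / "multi.pdb"
        path.write_text("\n".join(blocks) + "\nEND\n")
        return path

    def test_three_models(self, tmp_path):
        path = self._multi_model(tmp_path, 3)
        top = make_topology([backbone_residue(1, "ALA")])
        traj = read_trajectory(path, top)
        assert traj.n_frames == 3

    def test_stride_metadata(self, tmp_path):
        path = self._multi_model(tmp_path, 5)
        top = make_topology([backbone_residue(1, "ALA")])
        traj = read_trajectory(path, top, start_ns=0.0, stride_ns=0.1)
        np.testing.assert_allclose(traj.times, [0.0, 0.1, 0.2, 0.3, 0.4])

    def test_missing_atom_names_frame(self, tmp_path):
        path = self._multi_model(tmp_path, 3, drop_atom_in=2)
        top = make_topology([backbone_residue(1, "ALA")])
        with pytest.raises(ValueError, match="frame 2"):
            read_trajectory(path, top)


class TestTrajectoryInvariants:
    def test_atom_count_mismatch(self):
        top = make_topology([backbone_residue(1)])
        with pytest.raises(ValueError, match="atoms"):
            Trajectory(top, np.zeros((2, 3, 3)), np.array([0.0, 1.0]))

    def test_times_strictly_increasing(self):
        top = make_topology([backbone_residue(1)])
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(top, np.zeros((2, 4, 3)), np.array([1.0, 1.0]))


class TestRegionSpec:
    def test_first_after_last_rejected(self):
        with pytest.raises(ValueError, match="first > last"):
            RegionSpec([("transmembrane", 32, 12)])

    def test_conflicting_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            RegionSpec([("transmembrane", 10, 20), ("extracellular", 15, 25)])

    def test_same_label_disjoint_ranges_ok(self):
        spec = RegionSpec([("transmembrane", 10, 20), ("transmembrane", 30, 40)])
        assert spec.label_for(35) == "transmembrane"
        assert spec.label_for(25) is None


class TestAssignRegions:
    def _topology(self, seqs):
        return make_topology([backbone_residue(s, "ALA") for s in seqs])

    def test_residue_100_is_transmembrane(self):
        top = assign_regions(self._topology([100]), seven_tm_spec())
        assert top.region_of[("A", 100)] == "transmembrane"  # inside 93:113

    def test_residue_80_is_extracellular(self):
        top = assign_regions(self._topology([80]), seven_tm_spec())
        assert top.region_of[("A", 80)] == "extracellular"  # inside 64:92

    def test_uncovered_residue_gets_default(self):
        top = assign_regions(self._topology([40]), seven_tm_spec(),
                             default="cytoplasmic")
        assert top.region_of[("A", 40)] == "cytoplasmic"  # 33..42 gap

    def test_labels_partition_protein_residues(self):
        seqs = list(range(1, 306))
        spec = seven_tm_spec()
        top = assign_regions(self._topology(seqs), spec, default="cytoplasmic")
        counts = {}
        for key in top.residue_keys():
            counts[top.region_of[key]] = counts.get(top.region_of[key], 0) + 1
        assert sum(counts.values()) == len(seqs)
        tm = sum(b - a + 1 for a, b in TM_RANGES)
        ec = sum(b - a + 1 for a, b in EC_RANGES)
        assert counts["transmembrane"] == tm
        assert counts["extracellular"] == ec
        assert counts["cytoplasmic"] == len(seqs) - tm - ec


class TestSampleFrames:
    def test_discard_and_stride(self):
        times = np.arange(0, 101, dtype=float)  # 0..100 ns at 1 ns
        picked = sample_frames(times, discard_ns=20, stride_ns=20)
        assert [times[i] for i in picked] == [20, 40, 60, 80, 100]

    def test_stride_beyond_span(self):
        times = np.arange(0, 11, dtype=float)
        assert len(sample_frames(times, 0, 1000)) == 1

    def test_microsecond_enumeration(self):
        # frozen oracle: enumerate t in {200, 220, ..., 1000} -> 41 entries
        times = np.arange(0, 1001, dtype=float)
        expected = len([t for t in range(0, 1001) if t >= 200 and (t - 200) % 20 == 0])
        assert expected == 41
        assert len(sample_frames(times, 200, 20)) == 41

    def test_exclusive_boundary_variant(self):
        times = np.arange(0, 1001, dtype=float)
        picked = sample_frames(times, 200, 20, boundary="exclusive")
        assert times[picked[0]] == 201  # first frame strictly after discard
        assert len(picked) == 40

    def test_none_qualify_is_empty(self):
        assert sample_frames(np.array([0.0, 1.0]), 5.0, 1.0) == []

    def test_spacing_property(self, rng):
        times = np.sort(rng.uniform(0, 100, size=200))
        times = np.unique(times)
        picked = sample_frames(times, 10.0, 7.5)
        sampled = times[picked]
        assert np.all(np.diff(sampled) >= 7.5 - 1e-9)
        assert np.all(sampled >= 10.0)

    def test_bad_stride(self):
        with pytest.raises(ValueError):
            sample_frames(np.array([0.0, 1.0]), 0.0, 0.0)


def test_infer_element():
    assert infer_element("CA") == "C"  # atom-name context: alpha carbon
    assert infer_element("CL") == "Cl"
    assert infer_element("1HB") == "H"
    assert infer_element("OG1") == "O"
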