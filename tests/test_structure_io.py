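import numpy as np
import pytest

from tsrkit.structure_io import (
    ParseConfig,
    extract_sequence,
    read_calpha_structure,
    write_calpha_pdb,
    write_fasta,
)


def atom_line(serial, name, res, chain, seq, x, y, z, altloc=" ", occ=1.0,
              record="ATOM", element=None):
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name:^4}{altloc}{res:<3} {chain}{seq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


THREE_CA = "\n".join(
    [
        atom_line(1, "CA", "HIS", "A", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "GLU", "A", 2, 3.8, 0.0, 0.0),
        atom_line(3, "CA", "HIS", "A", 3, 6.0, 3.1, 0.0),
        "END",
    ]
) + "\n"


class TestParsing:
    def test_three_ca_lines_parse_in_order(self):
        s = read_calpha_structure(THREE_CA, "A", structure_id="toy")
        assert [r.aa_code for r in s.residues] == ["HIS", "GLU", "HIS"]
        assert list(s.positions) == [1, 2, 3]
        np.testing.assert_allclose(s.residues[1].coord, [3.8, 0.0, 0.0])
        assert s.parse_report.clean

    def test_altloc_keeps_highest_occupancy(self):
        text = "\n".join(
            [
                atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
                atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0, altloc="A", occ=0.4),
                atom_line(3, "CA", "GLY", "A", 2, 4.1, 0.0, 0.0, altloc="B", occ=0.6),
                atom_line(4, "CA", "SER", "A", 3, 7.6, 0.0, 0.0),
                "END",
            ]
        )
        s = read_calpha_structure(text, "A")
        assert len(s) == 3
        np.testing.assert_allclose(s.residues[1].coord, [4.1, 0.0, 0.0])

    def test_altloc_tie_takes_lexicographically_first(self):
        text = "\n".join(
            [
                atom_line(1, "CA", "GLY", "A", 1, 1.0, 0.0, 0.0, altloc="B", occ=0.5),
                atom_line(2, "CA", "GLY", "A", 1, 2.0, 0.0, 0.0, altloc="A", occ=0.5),
                "END",
            ]
        )
        s = read_calpha_structure(text, "A")
        np.testing.assert_allclose(s.residues[0].coord, [2.0, 0.0, 0.0])

    def test_zn_hetatm_is_captured_as_metal(self):
        text = THREE_CA.replace(
            "END",
            atom_line(9, "ZN", "ZN", "A", 90, 1.0, 2.0, 3.0,
                      record="HETATM", element="ZN") + "\nEND",
        )
        s = read_calpha_structure(text, "A")
        assert len(s.hetero_metals) == 1
        element, coord = s.hetero_metals[0]
        assert element == "ZN"
        np.testing.assert_allclose(coord, [1.0, 2.0, 3.0])

    def test_record_order_within_chain_is_irrelevant(self):
        lines = THREE_CA.strip().splitlines()[:-1]
        reordered = "\n".join([lines[2], lines[0], lines[1], "END"])
        a = read_calpha_structure(THREE_CA, "A")
        b = read_calpha_structure(reordered, "A")
        assert [r.seq_position for r in a.residues] == [r.seq_position for r in b.residues]
        np.testing.assert_allclose(a.coords, b.coords)

    def test_residue_without_ca_is_counted(self):
        text = "\n".join(
            [
                atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
                atom_line(2, "CB", "GLY", "A", 2, 3.8, 0.0, 0.0),
                atom_line(3, "CA", "SER", "A", 3, 7.6, 0.0, 0.0),
                "END",
            ]
        )
        s = read_calpha_structure(text, "A")
        assert len(s) == 2
        assert s.parse_report.missing_ca == 1

    def test_malformed_atom_line_is_skipped_and_counted(self):
        text = "ATOM      1  CA  ALA A   1      bogus\n" + THREE_CA
        s = read_calpha_structure(text, "A")
        assert len(s) == 3
        assert s.parse_report.malformed_lines == 1

    def test_mse_maps_to_met(self):
        text = "\n".join(
            [
                atom_line(1, "CA", "MSE", "A", 1, 0.0, 0.0, 0.0, record="HETATM"),
                atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
                "END",
            ]
        )
        s = read_calpha_structure(text, "A")
        assert s.residues[0].aa_code == "MET"
        s2 = read_calpha_structure(text, "A", ParseConfig(mse_to_met=False))
        assert [r.aa_code for r in s2.residues] == ["GLY"]
        assert s2.parse_report.nonstandard_skipped == 1

    def test_missing_chain_is_a_hard_error(self):
        with pytest.raises(ValueError, match="chain 'B'"):
            read_calpha_structure(THREE_CA, "B", structure_id="toy")

    def test_first_model_only(self):
        text = (
            "MODEL        1\n" + THREE_CA.replace("END", "ENDMDL") +
            "MODEL        2\n" +
            atom_line(9, "CA", "TRP", "A", 9, 50.0, 0.0, 0.0) +
            "\nENDMDL\nEND\n"
        )
        s = read_calpha_structure(text, "A")
        assert [r.aa_code for r in s.residues] == ["HIS", "GLU", "HIS"]


class TestRoundTrip:
    def test_write_then_read_preserves_residues(self, cys_triad_structure):
        structure, _, _ = cys_triad_structure
        text = write_calpha_pdb(structure)
        back = read_calpha_structure(text, structure.chain_id,
                                     structure_id=structure.structure_id)
        assert back.parse_report.clean
        assert [r.seq_position for r in back.residues] == [
            r.seq_position for r in structure.residues
        ]
        assert back.aa_codes == structure.aa_codes
        np.testing.assert_allclose(back.coords, structure.coords, atol=1e-3)


class TestSequence:
    def test_his_glu_his_reads_heh(self):
        s = read_calpha_structure(THREE_CA, "A")
        assert extract_sequence(s) == "HEH"

    def test_cys_gly_gly(self):
        text = THREE_CA.replace("HIS", "CYS").replace("GLU", "GLY")
        text = text.replace("CYS", "CYS", 1)
        s = read_calpha_structure(
            "\n".join(
                [
                    atom_line(1, "CA", "CYS", "A", 1, 0.0, 0.0, 0.0),
                    atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
                    atom_line(3, "CA", "GLY", "A", 3, 6.0, 3.1, 0.0),
                    "END",
                ]
            ),
            "A",
        )
        assert extract_sequence(s) == "CGG"

    def test_fasta_export(self, tmp_path):
        s = read_calpha_structure(THREE_CA, "A", structure_id="toy")
        path = tmp_path / "seqs.fasta"
        write_fasta([s], path)
        content = path.read_text()
        assert content.startswith(">toy_A")
        assert "HEH" in content
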