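import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tsrkit.keys import compute_key
from tsrkit.motif import (
    disulfide_pairs,
    extract_his_his_acid_triangles,
    find_hexxh,
    summarize_motif_geometry,
)
from tsrkit.structure_io import CalphaStructure, Residue
from tsrkit.synthetic_data import PlantedTriple, SyntheticSpec, generate_structure

from .conftest import random_rotation


class TestHexxh:
    @pytest.mark.parametrize(
        "sequence,expected",
        [
            ("AAHELTHAA", [3]),
            ("AAAAA", []),
            ("HEAAHEAAH", [1, 5]),  # overlapping matches both reported
            ("HEXXH", [1]),
            ("", []),
        ],
    )
    def test_examples(self, sequence, expected):
        assert find_hexxh(sequence) == expected

    @given(st.text(alphabet="HEAG", max_size=40))
    def test_matches_brute_force_substring_scan(self, seq):
        brute = [
            i + 1
            for i in range(len(seq) - 4)
            if seq[i] == "H" and seq[i + 1] == "E" and seq[i + 4] == "H"
        ]
        found = find_hexxh(seq)
        assert found == brute
        assert found == sorted(found)
        for p in found:
            assert seq[p - 1] == "H" and seq[p] == "E" and seq[p + 3] == "H"


@pytest.fixture(scope="module")
def zn_structure():
    """Planted Zn site (His-His-Glu + ZN) and a distant His-His-Asp triple."""
    spec = SyntheticSpec(
        n_residues=60,
        seed=21,
        planted=(
            PlantedTriple(("HIS", "GLU", "HIS"), (15, 18, 21),
                          max_dist=8.5, theta=50.0, zn_site=True),
            PlantedTriple(("HIS", "HIS", "ASP"), (40, 42, 45),
                          max_dist=11.0, theta=70.0),
        ),
        composition={"ALA": 1.0, "GLY": 1.0, "SER": 1.0},
    )
    return generate_structure(spec)[0]


class TestExtraction:
    def test_no_histidine_gives_no_triangles(self, ungrouped):
        s = CalphaStructure("x", "A")
        s.residues = [
            Residue(i + 1, "", aa, np.array([3.8 * i, 0.0, 0.0]))
            for i, aa in enumerate(["ALA", "GLU", "GLY"])
        ]
        assert extract_his_his_acid_triangles(s, ungrouped) == []

    def test_two_his_one_glu_gives_one_triangle(self, ungrouped):
        s = CalphaStructure("x", "A")
        coords = [[0, 0, 0], [5, 0, 0], [2, 4, 0]]
        for i, (aa, c) in enumerate(zip(["HIS", "HIS", "GLU"], coords)):
            s.residues.append(Residue(i + 1, "", aa, np.array(c, dtype=float)))
        triangles = extract_his_his_acid_triangles(s, ungrouped)
        assert len(triangles) == 1
        assert triangles[0].composition == "HHE"
        assert triangles[0].is_site is None  # no ZN, no annotation

    def test_planted_zn_site_is_classified_site(self, zn_structure, ungrouped):
        triangles = extract_his_his_acid_triangles(zn_structure, ungrouped)
        by_pos = {frozenset(t.triangle.vertex_positions): t for t in triangles}
        site = by_pos[frozenset({15, 18, 21})]
        assert site.composition == "HHE"
        assert site.is_site is True
        assert max(site.zn_distances) <= 3.0
        non_site = by_pos[frozenset({40, 42, 45})]
        assert non_site.composition == "HHD"
        assert non_site.is_site is False

    def test_annotation_fallback_for_apo_structures(self, zn_structure, ungrouped):
        apo = CalphaStructure(zn_structure.structure_id, "A")
        apo.residues = list(zn_structure.residues)  # drop metals and ligands
        triangles = extract_his_his_acid_triangles(
            apo, ungrouped, site_annotations=[(15, 18, 21)]
        )
        by_pos = {frozenset(t.triangle.vertex_positions): t for t in triangles}
        assert by_pos[frozenset({15, 18, 21})].is_site is True
        assert by_pos[frozenset({40, 42, 45})].is_site is False

    def test_site_classification_is_rigid_body_invariant(self, zn_structure, ungrouped, rng):
        before = {
            frozenset(t.triangle.vertex_positions): t.is_site
            for t in extract_his_his_acid_triangles(zn_structure, ungrouped)
        }
        moved = zn_structure.transformed(random_rotation(rng), rng.uniform(-40, 40, 3))
        after = {
            frozenset(t.triangle.vertex_positions): t.is_site
            for t in extract_his_his_acid_triangles(moved, ungrouped)
        }
        assert before == after

    def test_motif_keys_match_key_pipeline(self, zn_structure, ungrouped, fitted_bins):
        theta_bins, maxdist_bins = fitted_bins
        triangles = extract_his_his_acid_triangles(
            zn_structure, ungrouped, theta_bins, maxdist_bins
        )
        assert triangles
        for t in triangles:
            rec = t.triangle
            assert rec.key == compute_key(
                *rec.labels, rec.d_bin, rec.theta_bin, ungrouped,
                theta_bins.bin_count, maxdist_bins.bin_count,
            )


class TestSummary:
    def test_single_triangle_mean_is_itself(self, zn_structure, ungrouped):
        triangles = extract_his_his_acid_triangles(zn_structure, ungrouped)
        one = [t for t in triangles if t.is_site][:1]
        summary = summarize_motif_geometry(one)
        assert summary.loc["site", "max_dist_mean"] == pytest.approx(
            one[0].triangle.max_dist
        )
        assert "max_dist_q25" not in summary.columns

    def test_site_and_non_site_groups_separate(self, zn_structure, ungrouped):
        triangles = extract_his_his_acid_triangles(zn_structure, ungrouped)
        summary = summarize_motif_geometry(triangles)
        assert {"site", "non-site"} <= set(summary.index)
        # planted site at MaxDist 8.5; the planted non-site triple at 11.0
        assert summary.loc["site", "max_dist_mean"] == pytest.approx(8.5, abs=1e-6)

    def test_duplicated_triangles_have_zero_iqr(self, zn_structure, ungrouped):
        t = [x for x in extract_his_his_acid_triangles(zn_structure, ungrouped)
             if x.is_site][0]
        summary = summarize_motif_geometry([t, t, t])
        assert summary.loc["site", "max_dist_q25"] == summary.loc["site", "max_dist_q75"]

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no motif"):
            summarize_motif_geometry([])


def test_disulfide_pairs_report():
    s = CalphaStructure("x", "A")
    for i in range(4):
        s.residues.append(Residue(i + 1, "", "CYS", np.array([6.0 * i, 0.0, 0.0])))
    s.sidechain_atoms = [
        (1, "SG", np.array([0.0, 2.0, 0.0])),
        (2, "SG", np.array([0.0, 2.0, 2.05])),   # 2.05 A from residue 1's SG
        (3, "SG", np.array([12.0, 2.0, 0.0])),
        (4, "SG", np.array([30.0, 0.0, 0.0])),
    ]
    pairs = disulfide_pairs(s)
    assert [(p[0], p[1]) for p in pairs] == [(1, 2)]
    assert pairs[0][2] == pytest.approx(2.05)
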