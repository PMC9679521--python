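import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tsrkit.keys import (
    KeyVector,
    compute_key,
    decompose_key,
    key_vector,
    read_key_file,
    read_triplet_file,
    structure_triangles,
    write_key_file,
    write_triplet_file,
)
from tsrkit.structure_io import CalphaStructure, Residue

from .conftest import random_rotation


def make_structure(codes, coords, structure_id="toy"):
    s = CalphaStructure(structure_id=structure_id, chain_id="A")
    s.residues = [
        Residue(i + 1, "", code, np.asarray(c, dtype=float))
        for i, (code, c) in enumerate(zip(codes, coords))
    ]
    return s


class TestComputeKey:
    @pytest.mark.parametrize(
        "grouping,components,expected",
        [
            (True, (13, 13, 13, 7, 24), 2229137),   # Cys-Cys-Cys
            (True, (13, 6, 6, 2, 24), 2129522),     # Cys-Gly-Gly
            (False, (5, 5, 5, 7, 24), 1709457),     # Cys-Cys-Cys
            (False, (8, 5, 5, 4, 13), 2927359),     # Leu-Cys-Cys
            (False, (22, 9, 5, 5, 4), 8692579),     # Arg-His-Cys
        ],
    )
    def test_published_key_integers(self, grouping, components, expected, grouped, ungrouped):
        scheme = grouped if grouping else ungrouped
        assert compute_key(*components, scheme) == expected

    def test_minimal_components_give_key_zero(self, grouped):
        assert compute_key(1, 1, 1, 1, 1, grouped) == 0

    @pytest.mark.parametrize(
        "components,message",
        [
            ((5, 8, 5, 1, 1), "li1 >= li2"),
            ((25, 5, 5, 1, 1), "li1"),
            ((8, 5, 5, 36, 1), "d="),
            ((8, 5, 5, 1, 30), "theta"),
        ],
    )
    def test_invalid_components_rejected(self, components, message, ungrouped):
        with pytest.raises(ValueError, match=message):
            compute_key(*components, ungrouped)


class TestDecomposeKey:
    def test_published_keys_decode_to_their_compositions(self, grouped, ungrouped):
        assert decompose_key(2229137, grouped) == (13, 13, 13, 7, 24)
        assert decompose_key(2129522, grouped) == (13, 6, 6, 2, 24)
        assert decompose_key(8692579, ungrouped) == (22, 9, 5, 5, 4)

    def test_key_zero_is_the_minimal_tuple(self, grouped):
        assert decompose_key(0, grouped) == (1, 1, 1, 1, 1)

    def test_unrepresentable_key_is_rejected(self, grouped):
        top = compute_key(13, 13, 13, 35, 29, grouped)
        with pytest.raises(ValueError, match="not representable"):
            decompose_key(top + 1, grouped)

    @given(data=st.data())
    def test_round_trip_over_admissible_tuples(self, grouped, ungrouped, data):
        scheme = data.draw(st.sampled_from(["g", "u"]))
        scheme = {"g": grouped, "u": ungrouped}[scheme]
        lo, hi = scheme.label_range
        labels = sorted(
            data.draw(st.tuples(*(st.integers(lo, hi),) * 3)), reverse=True
        )
        d = data.draw(st.integers(1, 35))
        t = data.draw(st.integers(1, 29))
        key = compute_key(*labels, d, t, scheme)
        assert decompose_key(key, scheme) == (*labels, d, t)


class TestKeyVector:
    def test_three_residues_give_one_triangle(self, ungrouped, fitted_bins):
        theta_bins, maxdist_bins = fitted_bins
        s = make_structure(
            ["ALA", "GLY", "SER"], [[0, 0, 0], [3.8, 0, 0], [2.0, 3.3, 0]]
        )
        kv = key_vector(s, ungrouped, theta_bins, maxdist_bins)
        assert kv.triangle_total == 1
        assert sum(kv.counts.values()) == 1

    def test_triangle_total_is_n_choose_3(self, cys_triad_structure, ungrouped, fitted_bins):
        structure, _, _ = cys_triad_structure
        kv = key_vector(structure, ungrouped, *fitted_bins)
        n = len(structure)
        assert kv.triangle_total == n * (n - 1) * (n - 2) // 6
        assert sum(kv.counts.values()) == kv.triangle_total

    def test_fewer_than_three_residues_is_an_error(self, ungrouped, fitted_bins):
        s = make_structure(["ALA", "GLY"], [[0, 0, 0], [3.8, 0, 0]])
        with pytest.raises(ValueError, match="need >= 3"):
            key_vector(s, ungrouped, *fitted_bins)

    def test_rigid_body_invariance(self, cys_triad_structure, ungrouped, fitted_bins, rng):
        structure, _, _ = cys_triad_structure
        reference = key_vector(structure, ungrouped, *fitted_bins)
        for _ in range(3):
            moved = structure.transformed(
                random_rotation(rng), rng.uniform(-100, 100, 3)
            )
            assert key_vector(moved, ungrouped, *fitted_bins).counts == reference.counts

    def test_scale_sensitivity(self, cys_triad_structure, ungrouped, fitted_bins):
        structure, _, _ = cys_triad_structure
        reference = key_vector(structure, ungrouped, *fitted_bins)
        with pytest.warns(UserWarning):
            scaled = key_vector(
                structure.transformed(2.0 * np.eye(3)), ungrouped, *fitted_bins
            )
        assert scaled.counts != reference.counts

    def test_triangle_keys_recompute_from_components(self, ungrouped, fitted_bins):
        theta_bins, maxdist_bins = fitted_bins
        rng = np.random.default_rng(9)
        s = make_structure(
            ["CYS", "HIS", "ARG", "GLY", "TRP"], rng.uniform(0, 15, (5, 3))
        )
        frame = structure_triangles(s, ungrouped, theta_bins, maxdist_bins)
        for row in frame.itertuples():
            assert row.key == compute_key(
                row.li1, row.li2, row.li3, row.d_bin, row.theta_bin, ungrouped
            )


class TestFileFormats:
    def test_key_file_round_trip(self, tmp_path):
        kv = KeyVector("s1", "ungrouped", {42: 3, 7: 1}, triangle_total=4)
        path = tmp_path / "s1.keys.tsv"
        write_key_file(kv, path)
        assert read_key_file(path) == kv

    def test_empty_key_vector_round_trip(self, tmp_path):
        kv = KeyVector("s2", "grouped", {}, triangle_total=0)
        path = tmp_path / "s2.keys.tsv"
        write_key_file(kv, path)
        assert read_key_file(path) == kv

    def test_malformed_key_file_is_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("key\tfrequency\n1\t2\n")
        with pytest.raises(ValueError, match="header"):
            read_key_file(path)

    def test_triplet_file_round_trip(self, tmp_path, cys_triad_structure,
                                     ungrouped, fitted_bins):
        structure, _, _ = cys_triad_structure
        frame = structure_triangles(structure, ungrouped, *fitted_bins)
        path = tmp_path / "s.triplets.tsv"
        write_triplet_file(frame, path)
        back = read_triplet_file(path)
        assert len(back) == len(frame)
        assert back.attrs["structure_id"] == structure.structure_id
        np.testing.assert_array_equal(back["key"], frame["key"])
        np.testing.assert_allclose(back["max_dist"], frame["max_dist"], atol=1e-6)
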