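"""Integer TSR keys: encoding, decoding, and per-structure key vectors.

A triangle with role-ordered labels (li1 ≥ li2 ≥ li3), MaxDist bin d
(1..dT) and Theta bin θ (1..θT) is encoded as the single integer

    k = θT·dT·[ (li1−1)·m² + (li2−1)·m + (li3−1) ] + θT·(d−1) + (θ−1)

where m is the number of distinct labels of the scheme.  Because every
scheme's label range has width ≤ m, the mixed-radix digits (li−1) are
recoverable from k even when they exceed m−1 (the ungrouped scheme uses
labels 4..23 with m = 20), so the encoding is injective and exactly
invertible.  All arithmetic is exact integer arithmetic.

A structure's :class:`KeyVector` is the multiset of keys over all
C(n, 3) Cα triples; degenerate triangles (undefined angle) are excluded
and counted.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discretization import (
    MAXDIST_BIN_COUNT,
    THETA_BIN_COUNT,
    BinBoundaries,
    assign_bins,
)
from .geometry import GEOMETRY_DECIMALS, triangle_geometry_arrays
from .labeling import LabelScheme

__all__ = [
    "KeyVector",
    "compute_key",
    "compute_keys_array",
    "decompose_key",
    "key_vector",
    "structure_triangles",
    "pooled_geometry",
    "write_key_file",
    "read_key_file",
    "write_triplet_file",
    "read_triplet_file",
]

TRIPLET_COLUMNS = [
    "res_i", "res_j", "res_k", "li1", "li2", "li3",
    "d12", "d13", "d3", "max_dist", "theta", "d_bin", "theta_bin", "key",
]


@dataclass
class KeyVector:
    """Key → occurrence frequency for one structure under one scheme."""

    structure_id: str
    scheme_name: str
    counts: dict[int, int] = field(default_factory=dict)
    triangle_total: int = 0
    degenerate_count: int = 0

    @property
    def distinct_keys(self) -> set[int]:
        return set(self.counts)

    def __eq__(self, other):
        if not isinstance(other, KeyVector):
            return NotImplemented
        return (
            self.structure_id == other.structure_id
            and self.scheme_name == other.scheme_name
            and self.counts == other.counts
            and self.triangle_total == other.triangle_total
        )


def _check_component(name, value, lo, hi):
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside admissible range [{lo}, {hi}]")


def compute_key(li1, li2, li3, d, theta, scheme: LabelScheme,
                theta_bins: int = THETA_BIN_COUNT,
                dist_bins: int = MAXDIST_BIN_COUNT) -> int:
    """Encode one triangle; validates every component."""
    lo, hi = scheme.label_range
    _check_component("li1", li1, lo, hi)
    _check_component("li2", li2, lo, hi)
    _check_component("li3", li3, lo, hi)
    if not li1 >= li2 >= li3:
        raise ValueError(f"labels must satisfy li1 >= li2 >= li3, got {(li1, li2, li3)}")
    _check_component("d", d, 1, dist_bins)
    _check_component("theta", theta, 1, theta_bins)
    m = scheme.m
    block = theta_bins * dist_bins
    return (
        block * ((li1 - 1) * m * m + (li2 - 1) * m + (li3 - 1))
        + theta_bins * (d - 1)
        + (theta - 1)
    )


def compute_keys_array(li1, li2, li3, d, theta, scheme: LabelScheme,
                       theta_bins: int = THETA_BIN_COUNT,
                       dist_bins: int = MAXDIST_BIN_COUNT) -> np.ndarray:
    """Vectorized encoding (inputs already validated upstream)."""
    m = np.int64(scheme.m)
    block = np.int64(theta_bins * dist_bins)
    li1 = np.asarray(li1, dtype=np.int64)
    li2 = np.asarray(li2, dtype=np.int64)
    li3 = np.asarray(li3, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    theta = np.asarray(theta, dtype=np.int64)
    return (
        block * ((li1 - 1) * m * m + (li2 - 1) * m + (li3 - 1))
        + theta_bins * (d - 1)
        + (theta - 1)
    )


def _digit_from_residue(r, lo, hi, m):
    """The unique value in [lo, hi] congruent to r modulo m."""
    digit = r + m * ((lo - r + m - 1) // m)
    if digit > hi:
        raise ValueError("key not representable under scheme")
    return digit


def decompose_key(k: int, scheme: LabelScheme,
                  theta_bins: int = THETA_BIN_COUNT,
                  dist_bins: int = MAXDIST_BIN_COUNT):
    """Invert :func:`compute_key`; returns (li1, li2, li3, d, theta).

    Uniqueness follows from the label-range width being at most m: in
    each mixed-radix digit position there is exactly one admissible
    value in a given congruence class modulo m.
    """
    if k < 0:
        raise ValueError("keys are non-negative")
    block = theta_bins * dist_bins
    rem = k % block
    d = rem // theta_bins + 1
    theta = rem % theta_bins + 1
    if d > dist_bins:
        raise ValueError("key not representable under scheme")
    m = scheme.m
    lo, hi = scheme.min_label - 1, scheme.max_label - 1
    level = k // block
    digits = []
    for _ in range(3):
        r = level % m
        digit = _digit_from_residue(r, lo, hi, m)
        digits.append(digit)
        level = (level - digit) // m
    if level != 0:
        raise ValueError("key not representable under scheme")
    li3, li2, li1 = (digit + 1 for digit in digits)
    if not li1 >= li2 >= li3:
        raise ValueError("key not representable under scheme")
    return li1, li2, li3, int(d), int(theta)


def decompose_keys_array(keys, scheme: LabelScheme,
                         theta_bins: int = THETA_BIN_COUNT,
                         dist_bins: int = MAXDIST_BIN_COUNT):
    """Vectorized inverse of :func:`compute_keys_array` (assumes validity)."""
    keys = np.asarray(keys, dtype=np.int64)
    block = theta_bins * dist_bins
    rem = keys % block
    d = rem // theta_bins + 1
    theta = rem % theta_bins + 1
    m = scheme.m
    lo = scheme.min_label - 1
    level = keys // block
    out = []
    for _ in range(3):
        r = level % m
        digit = r + m * ((lo - r + m - 1) // m)
        out.append(digit + 1)
        level = (level - digit) // m
    li3, li2, li1 = out
    return li1, li2, li3, d, theta


def _combination_indices(n: int) -> np.ndarray:
    combs = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), 3)),
        dtype=np.intp,
    )
    return combs.reshape(-1, 3)


def _assign_roles(labels, precedence, positions, combs, coords):
    """Vectorized role assignment for all triples.

    Chooses, per triple, the vertex permutation maximizing the tuple
    (L1, L2, L3, P1, P2, P3, d12, d13, -pos1) lexicographically — i.e.
    labels descending, ties by canonical precedence, then the
    d12-maximizing / d13-maximizing geometric rule, then lowest
    sequence position in role 1.  Returns role-ordered vertex indices
    (i1, i2, i3) arrays.
    """
    n_tri = len(combs)
    pts = coords[combs]  # (N, 3, 3)
    # pairwise distances inside each triple, indexed by vertex-slot pair
    dmat = np.zeros((n_tri, 3, 3))
    for a, b in itertools.combinations(range(3), 2):
        dd = np.linalg.norm(pts[:, a] - pts[:, b], axis=1)
        dmat[:, a, b] = dd
        dmat[:, b, a] = dd

    perms = list(itertools.permutations(range(3)))
    lab = labels[combs]         # (N, 3)
    prec = precedence[combs]
    pos = positions[combs]

    components = []  # each: (N, 6)
    for comp in range(9):
        col = np.empty((n_tri, len(perms)))
        for pi, p in enumerate(perms):
            if comp < 3:
                col[:, pi] = lab[:, p[comp]]
            elif comp < 6:
                col[:, pi] = prec[:, p[comp - 3]]
            elif comp == 6:
                col[:, pi] = dmat[:, p[0], p[1]]
            elif comp == 7:
                col[:, pi] = dmat[:, p[0], p[2]]
            else:
                col[:, pi] = -pos[:, p[0]]
        components.append(col)

    active = np.ones((n_tri, len(perms)), dtype=bool)
    for col in components:
        masked = np.where(active, col, -np.inf)
        best = masked.max(axis=1, keepdims=True)
        active &= masked == best
    chosen = np.argmax(active, axis=1)

    perm_arr = np.array(perms, dtype=np.intp)  # (6, 3)
    roles = perm_arr[chosen]                   # (N, 3) slot index per role
    i1 = combs[np.arange(n_tri), roles[:, 0]]
    i2 = combs[np.arange(n_tri), roles[:, 1]]
    i3 = combs[np.arange(n_tri), roles[:, 2]]
    return i1, i2, i3


def structure_triangles(structure, scheme: LabelScheme,
                        theta_bins: BinBoundaries | None = None,
                        maxdist_bins: BinBoundaries | None = None) -> pd.DataFrame:
    """All non-degenerate triangles of a structure as a DataFrame.

    Columns follow the triplet-file layout; ``res_i`` is the residue
    sequence position in the li1 role (the stored order records the
    vertex permutation).  Bin and key columns are present only when
    boundaries are supplied.  The frame's ``attrs`` carry the count of
    excluded degenerate triangles.
    """
    n = len(structure.residues)
    if n < 3:
        raise ValueError(
            f"structure {structure.structure_id} has {n} residues; need >= 3"
        )
    coords = structure.coords
    positions = structure.positions
    aa = structure.aa_codes
    labels = scheme.labels_for(aa)
    precedence = scheme.precedence_for(aa)

    combs = _combination_indices(n)
    i1, i2, i3 = _assign_roles(labels, precedence, positions, combs, coords)
    d12, d13, d3, max_dist, theta, degen = triangle_geometry_arrays(
        coords[i1], coords[i2], coords[i3]
    )
    keep = ~degen
    frame = pd.DataFrame(
        {
            "res_i": positions[i1][keep],
            "res_j": positions[i2][keep],
            "res_k": positions[i3][keep],
            "li1": labels[i1][keep],
            "li2": labels[i2][keep],
            "li3": labels[i3][keep],
            "d12": d12[keep],
            "d13": d13[keep],
            "d3": d3[keep],
            "max_dist": np.round(max_dist[keep], GEOMETRY_DECIMALS),
            "theta": np.round(theta[keep], GEOMETRY_DECIMALS),
        }
    )
    frame.attrs["degenerate_count"] = int(degen.sum())
    frame.attrs["structure_id"] = structure.structure_id
    frame.attrs["scheme_name"] = scheme.name
    if theta_bins is not None and maxdist_bins is not None:
        frame["d_bin"] = assign_bins(frame["max_dist"].to_numpy(), maxdist_bins)
        frame["theta_bin"] = assign_bins(frame["theta"].to_numpy(), theta_bins)
        frame["key"] = compute_keys_array(
            frame["li1"], frame["li2"], frame["li3"],
            frame["d_bin"], frame["theta_bin"],
            scheme, theta_bins.bin_count, maxdist_bins.bin_count,
        )
        frame.attrs["theta_bin_count"] = theta_bins.bin_count
        frame.attrs["dist_bin_count"] = maxdist_bins.bin_count
    return frame


def key_vector(structure, scheme: LabelScheme,
               theta_bins: BinBoundaries,
               maxdist_bins: BinBoundaries) -> KeyVector:
    """Key-frequency vector over all C(n, 3) Cα triples of a structure."""
    frame = structure_triangles(structure, scheme, theta_bins, maxdist_bins)
    keys, counts = np.unique(frame["key"].to_numpy(), return_counts=True)
    return KeyVector(
        structure_id=structure.structure_id,
        scheme_name=scheme.name,
        counts={int(k): int(c) for k, c in zip(keys, counts)},
        triangle_total=int(len(frame)),
        degenerate_count=frame.attrs["degenerate_count"],
    )


def pooled_geometry(structures, scheme: LabelScheme):
    """Concatenated (max_dist, theta) arrays over several structures.

    Used to fit dataset-level bin boundaries before key generation.
    """
    md, th = [], []
    for s in structures:
        frame = structure_triangles(s, scheme)
        md.append(frame["max_dist"].to_numpy())
        th.append(frame["theta"].to_numpy())
    return np.concatenate(md), np.concatenate(th)


# ---------------------------------------------------------------------------
# file formats (tab-separated, '#'-prefixed header line)

def _header(structure_id, scheme_name, theta_bins, dist_bins):
    return f"# {structure_id} {scheme_name} {theta_bins} {dist_bins}\n"


def write_key_file(vector: KeyVector, path,
                   theta_bins: int = THETA_BIN_COUNT,
                   dist_bins: int = MAXDIST_BIN_COUNT) -> None:
    with open(path, "w") as fh:
        fh.write(_header(vector.structure_id, vector.scheme_name, theta_bins, dist_bins))
        fh.write("key\tfrequency\n")
        for key in sorted(vector.counts):
            fh.write(f"{key}\t{vector.counts[key]}\n")


def read_key_file(path) -> KeyVector:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError(f"{path}:1: missing '# structure_id scheme ...' header")
        fields = header[2:].split()
        if len(fields) != 4:
            raise ValueError(f"{path}:1: malformed header")
        structure_id, scheme_name = fields[0], fields[1]
        body = fh.read()
    frame = pd.read_csv(io.StringIO(body), sep="\t")
    if list(frame.columns) != ["key", "frequency"]:
        raise ValueError(f"{path}:2: expected columns key, frequency")
    counts = {int(k): int(c) for k, c in zip(frame["key"], frame["frequency"])}
    return KeyVector(
        structure_id=structure_id,
        scheme_name=scheme_name,
        counts=counts,
        triangle_total=int(frame["frequency"].sum()),
    )


def write_triplet_file(frame: pd.DataFrame, path) -> None:
    missing = [c for c in TRIPLET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"triplet frame misses columns {missing}")
    with open(path, "w") as fh:
        fh.write(
            _header(
                frame.attrs.get("structure_id", "?"),
                frame.attrs.get("scheme_name", "?"),
                frame.attrs.get("theta_bin_count", THETA_BIN_COUNT),
                frame.attrs.get("dist_bin_count", MAXDIST_BIN_COUNT),
            )
        )
        frame.to_csv(fh, sep="\t", index=False, columns=TRIPLET_COLUMNS,
                     float_format="%.6f")


def read_triplet_file(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError(f"{path}:1: missing header")
        fields = header[2:].split()
        frame = pd.read_csv(fh, sep="\t")
    if list(frame.columns) != TRIPLET_COLUMNS:
        raise ValueError(f"{path}: unexpected columns {list(frame.columns)}")
    frame.attrs["structure_id"] = fields[0]
    frame.attrs["scheme_name"] = fields[1]
    frame.attrs["theta_bin_count"] = int(fields[2])
    frame.attrs["dist_bin_count"] = int(fields[3])
    return frame
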