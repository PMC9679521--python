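"""Amino-acid label schemes and deterministic vertex-role ordering.

Each Cα vertex of a triangle carries an integer label derived from its
amino acid.  Two schemes ship with the package:

* **ungrouped** — every one of the 20 standard amino acids gets its own
  label in the contiguous range 4..23.
* **grouped** — a reduced 13-category alphabet in which seven
  physicochemically similar pairs (Ser/Thr, Ala/Val, Leu/Ile, Phe/Trp,
  Asp/Glu, Asn/Gln, Lys/Arg) share a label; labels span 1..13.

The integer assignments are anchored by the published key integers that
can be decoded unambiguously (Cys=5, Leu=8, His=9, Arg=22 ungrouped;
Cys=13, Gly=6 grouped).  The remaining assignments are the package's own
defaults, chosen so that the two schemes rank amino acids consistently
wherever the anchors permit, and can be overridden with a mapping file.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelScheme",
    "build_label_scheme",
    "load_label_table",
    "order_vertex_labels",
    "AA_THREE_TO_ONE",
    "AA_ONE_TO_THREE",
    "STANDARD_AMINO_ACIDS",
    "MERGED_PAIRS",
    "UNGROUPED_TABLE",
    "GROUPED_TABLE",
]

STANDARD_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}

#: The seven merged pairs of the grouped (13-category) alphabet.
MERGED_PAIRS = frozenset(
    frozenset(p)
    for p in [
        ("SER", "THR"), ("ALA", "VAL"), ("LEU", "ILE"), ("PHE", "TRP"),
        ("ASP", "GLU"), ("ASN", "GLN"), ("LYS", "ARG"),
    ]
)

# Default 20-label table (contiguous 4..23).  Anchored: CYS=5, LEU=8,
# HIS=9, ARG=22.  Merged pairs occupy adjacent labels so that collapsing
# them to the 13-category table below preserves the between-category order.
UNGROUPED_TABLE = {
    "MET": 4, "CYS": 5, "PRO": 6, "ILE": 7, "LEU": 8, "HIS": 9,
    "TYR": 10, "GLY": 11, "ALA": 12, "VAL": 13, "ASP": 14, "GLU": 15,
    "PHE": 16, "TRP": 17, "ASN": 18, "GLN": 19, "SER": 20, "THR": 21,
    "ARG": 22, "LYS": 23,
}

# Default 13-label table (contiguous 1..13).  Anchored: CYS=13, GLY=6.
GROUPED_TABLE = {
    "MET": 1, "PRO": 2, "LEU": 3, "ILE": 3, "HIS": 4, "TYR": 5,
    "GLY": 6, "ALA": 7, "VAL": 7, "ASP": 8, "GLU": 8, "PHE": 9,
    "TRP": 9, "ASN": 10, "GLN": 10, "SER": 11, "THR": 11, "ARG": 12,
    "LYS": 12, "CYS": 13,
}


@dataclass(frozen=True)
class LabelScheme:
    """An amino-acid → integer label map plus the derived quantities the
    key formula needs.

    Attributes
    ----------
    name : str
        ``"ungrouped"``, ``"grouped"`` or a custom name.
    mapping : dict
        Three-letter residue code → integer label.
    precedence : dict
        Three-letter residue code → canonical rank used to break role
        ties between *different* residues that share a label (only
        possible under grouping).  Defaults to the ungrouped labels.
    """

    name: str
    mapping: dict[str, int]
    precedence: dict[str, int] = field(default_factory=dict)

    @property
    def m(self) -> int:
        """Number of distinct labels (the radix of the key formula)."""
        return len(set(self.mapping.values()))

    @property
    def label_range(self) -> tuple[int, int]:
        labels = self.mapping.values()
        return (min(labels), max(labels))

    @property
    def min_label(self) -> int:
        return self.label_range[0]

    @property
    def max_label(self) -> int:
        return self.label_range[1]

    def labels_for(self, aa_codes) -> np.ndarray:
        return np.array([self.mapping[c] for c in aa_codes], dtype=np.int64)

    def precedence_for(self, aa_codes) -> np.ndarray:
        prec = self.precedence or self.mapping
        return np.array([prec[c] for c in aa_codes], dtype=np.int64)


def _validate(name: str, mapping: dict[str, int], grouping: bool) -> None:
    missing = set(STANDARD_AMINO_ACIDS) - set(mapping)
    if missing:
        raise ValueError(f"label table for scheme '{name}' misses {sorted(missing)}")
    labels = sorted(set(mapping.values()))
    lo, hi = labels[0], labels[-1]
    m = len(labels)
    if labels != list(range(lo, hi + 1)):
        raise ValueError(f"scheme '{name}': labels {labels} are not contiguous")
    if hi - lo + 1 > m:
        raise ValueError(
            f"scheme '{name}': label range width {hi - lo + 1} exceeds m={m}; "
            "keys would not decode uniquely"
        )
    if grouping:
        if m != 13:
            raise ValueError(f"grouped scheme must have 13 labels, got {m}")
        for pair in MERGED_PAIRS:
            a, b = sorted(pair)
            if mapping[a] != mapping[b]:
                raise ValueError(
                    f"grouped scheme must merge {a}/{b} into one label "
                    f"(got {mapping[a]} and {mapping[b]})"
                )
        # no accidental extra merges
        by_label: dict[int, set[str]] = {}
        for aa, lab in mapping.items():
            by_label.setdefault(lab, set()).add(aa)
        for lab, members in by_label.items():
            if len(members) > 1 and frozenset(members) not in MERGED_PAIRS:
                raise ValueError(
                    f"label {lab} merges {sorted(members)}, which is not one "
                    "of the seven allowed pairs"
                )
    else:
        if m != 20:
            raise ValueError(f"ungrouped scheme must have 20 distinct labels, got {m}")


def load_label_table(path) -> dict[str, int]:
    """Read a two-column ``AAA<TAB>integer`` mapping file ('#' comments)."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'AAA<TAB>label'")
            aa, lab = parts[0].upper(), parts[1]
            mapping[aa] = int(lab)
    return mapping


def build_label_scheme(grouping: bool = False, mapping_table=None, name=None) -> LabelScheme:
    """Return a validated :class:`LabelScheme`.

    Parameters
    ----------
    grouping : bool
        If True, use (or validate a custom table as) the 13-category
        reduced alphabet; otherwise the 20-label alphabet.
    mapping_table : str | dict, optional
        Path to a mapping file, or a dict, overriding the default table.
    """
    if mapping_table is None:
        mapping = dict(GROUPED_TABLE if grouping else UNGROUPED_TABLE)
        default_name = "grouped" if grouping else "ungrouped"
    else:
        mapping = (
            dict(mapping_table)
            if isinstance(mapping_table, dict)
            else load_label_table(mapping_table)
        )
        default_name = "custom-grouped" if grouping else "custom"
    scheme_name = name or default_name
    _validate(scheme_name, mapping, grouping)
    return LabelScheme(name=scheme_name, mapping=mapping, precedence=dict(UNGROUPED_TABLE))


#: the six permutations of three vertices, in a fixed order
_PERMS = tuple(itertools.permutations(range(3)))


def order_vertex_labels(labels, coords, positions=None, precedence=None):
    """Assign the three triangle vertices to the roles (li1, li2, li3).

    Roles are chosen by sorting labels in descending order; ties are
    broken by canonical residue precedence (descending), then by
    maximizing d12, then d13, and finally by the lowest sequence
    position in the li1 role.  The rule depends on coordinates only
    through pairwise distances, so it is rigid-body invariant.

    Returns
    -------
    (li1, li2, li3) : tuple of int
    perm : tuple of int
        ``perm[r]`` is the input index of the vertex assigned to role r.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    if positions is None:
        positions = np.arange(3)
    else:
        positions = np.asarray(positions)
    if precedence is None:
        precedence = labels
    else:
        precedence = np.asarray(precedence)

    dist = {
        (i, j): float(np.linalg.norm(coords[i] - coords[j]))
        for i, j in itertools.combinations(range(3), 2)
    }
    dist.update({(j, i): v for (i, j), v in dist.items()})

    best_key, best_perm = None, None
    for p in _PERMS:
        key = (
            labels[p[0]], labels[p[1]], labels[p[2]],
            precedence[p[0]], precedence[p[1]], precedence[p[2]],
            dist[(p[0], p[1])], dist[(p[0], p[2])],
            -int(positions[p[0]]),
        )
        if best_key is None or key > best_key:
            best_key, best_perm = key, p
    p = best_perm
    return (int(labels[p[0]]), int(labels[p[1]]), int(labels[p[2]])), p
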