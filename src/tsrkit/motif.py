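"""Zn²⁺ binding-site geometry screening.

Zinc proteases coordinate the catalytic Zn²⁺ through two histidines and
one glutamate or aspartate; thermolysin-family enzymes and ACE/ACE2
additionally carry the HExxH sequence motif that contributes the two
histidines.  This module

* scans sequences for HExxH (overlaps included),
* extracts every His-His-(Glu|Asp) Cα triangle of a structure with the
  full key-pipeline geometry,
* classifies each triangle as a Zn site when all three residues have a
  side-chain ligand atom (His ND1/NE2, Glu OE1/OE2, Asp OD1/OD2) within
  a cutoff of the same ZN record (default 3.0 Å — typical Zn–N/O bonds
  are 2.0–2.3 Å), falling back to a user-supplied site annotation for
  apo structures, and
* summarizes MaxDist/Theta distributions for site vs non-site triangles.

Triangle geometry uses Cα positions, consistent with the key pipeline;
side-chain atoms serve only for site assignment.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretization import BinBoundaries, assign_bin
from .geometry import GEOMETRY_DECIMALS, TriangleRecord, triangle_geometry
from .keys import compute_key
from .labeling import LabelScheme, order_vertex_labels
from .structure_io import CalphaStructure

__all__ = [
    "MotifTriangle",
    "find_hexxh",
    "extract_his_his_acid_triangles",
    "summarize_motif_geometry",
    "disulfide_pairs",
    "DEFAULT_ZN_CUTOFF",
]

DEFAULT_ZN_CUTOFF = 3.0  # Å, Zn to side-chain N/O ligand atom

_LIGAND_ATOMS = {"HIS": ("ND1", "NE2"), "GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}

_HEXXH = re.compile(r"(?=HE..H)")


@dataclass
class MotifTriangle:
    """One two-His-one-acid triangle with its site classification.

    ``is_site`` is True/False when resolvable from ZN records or an
    annotation list, or None ("unassigned") when neither is available.
    """

    triangle: TriangleRecord
    composition: str  # "HHE" or "HHD"
    is_site: bool | None
    zn_distances: list[float] | None = None


def find_hexxh(sequence: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) HExxH matches."""
    return [m.start() + 1 for m in _HEXXH.finditer(sequence.upper())]


def _ligand_distances(structure, seq_position, aa_code, zn_coord):
    names = _LIGAND_ATOMS[aa_code]
    dists = [
        float(np.linalg.norm(coord - zn_coord))
        for pos, name, coord in structure.sidechain_atoms
        if pos == seq_position and name in names
    ]
    return min(dists) if dists else None


def extract_his_his_acid_triangles(
    structure: CalphaStructure,
    scheme: LabelScheme,
    theta_bins: BinBoundaries | None = None,
    maxdist_bins: BinBoundaries | None = None,
    zn_cutoff: float = DEFAULT_ZN_CUTOFF,
    site_annotations=None,
) -> list[MotifTriangle]:
    """All {His, His, Glu-or-Asp} residue triples as :class:`MotifTriangle`.

    ``site_annotations`` is an iterable of residue-position triples known
    to form Zn sites; it is consulted when ZN-based assignment is not
    possible (apo structures or missing side-chain atoms).
    """
    annotations = {frozenset(t) for t in site_annotations} if site_annotations else set()
    his = [r for r in structure.residues if r.aa_code == "HIS"]
    acids = [r for r in structure.residues if r.aa_code in ("GLU", "ASP")]
    zn_coords = [c for e, c in structure.hetero_metals if e == "ZN"]

    out: list[MotifTriangle] = []
    for (h1, h2), acid in itertools.product(
        itertools.combinations(his, 2), acids
    ):
        residues = (h1, h2, acid)
        labels = scheme.labels_for([r.aa_code for r in residues])
        precedence = scheme.precedence_for([r.aa_code for r in residues])
        coords = np.array([r.coord for r in residues])
        positions = [r.seq_position for r in residues]
        ordered, perm = order_vertex_labels(labels, coords, positions, precedence)
        role_coords = coords[list(perm)]
        try:
            d12, d13, d3, max_dist, theta = triangle_geometry(role_coords)
        except ValueError:
            continue
        record = TriangleRecord(
            vertex_positions=tuple(positions[i] for i in perm),
            labels=ordered,
            d12=d12, d13=d13, d3=d3,
            max_dist=round(max_dist, GEOMETRY_DECIMALS),
            theta=round(theta, GEOMETRY_DECIMALS),
        )
        if theta_bins is not None and maxdist_bins is not None:
            record.d_bin = assign_bin(record.max_dist, maxdist_bins)
            record.theta_bin = assign_bin(record.theta, theta_bins)
            record.key = compute_key(
                *ordered, record.d_bin, record.theta_bin, scheme,
                theta_bins.bin_count, maxdist_bins.bin_count,
            )

        is_site: bool | None = None
        zn_dists = None
        if zn_coords:
            best = None
            for zn in zn_coords:
                dists = [
                    _ligand_distances(structure, r.seq_position, r.aa_code, zn)
                    for r in residues
                ]
                if any(d is None for d in dists):
                    continue
                if best is None or max(dists) < max(best):
                    best = dists
            if best is not None:
                zn_dists = best
                is_site = max(best) <= zn_cutoff
        if is_site is None and annotations:
            is_site = frozenset(positions) in annotations
        out.append(
            MotifTriangle(
                triangle=record,
                composition="HHE" if acid.aa_code == "GLU" else "HHD",
                is_site=is_site,
                zn_distances=zn_dists,
            )
        )
    return out


def summarize_motif_geometry(triangles) -> pd.DataFrame:
    """Mean and quartiles of MaxDist/Theta per site class.

    Rows are indexed by site class ("site", "non-site", "unassigned");
    groups with fewer than two triangles report the mean only.
    """
    triangles = list(triangles)
    if not triangles:
        raise ValueError("no motif triangles to summarize")
    rows = []
    for t in triangles:
        group = {True: "site", False: "non-site", None: "unassigned"}[t.is_site]
        rows.append(
            {"group": group, "max_dist": t.triangle.max_dist, "theta": t.triangle.theta}
        )
    frame = pd.DataFrame(rows)
    stats = []
    for group, sub in frame.groupby("group"):
        entry = {
            "group": group,
            "n": len(sub),
            "max_dist_mean": sub["max_dist"].mean(),
            "theta_mean": sub["theta"].mean(),
        }
        if len(sub) >= 2:
            for var in ("max_dist", "theta"):
                q = sub[var].quantile([0.25, 0.5, 0.75])
                entry[f"{var}_q25"] = q.loc[0.25]
                entry[f"{var}_median"] = q.loc[0.5]
                entry[f"{var}_q75"] = q.loc[0.75]
        stats.append(entry)
    return pd.DataFrame(stats).set_index("group")


def disulfide_pairs(structure: CalphaStructure, threshold: float = 2.20) -> list[tuple]:
    """Cys SG–SG pairs closer than ``threshold`` Å (disulfide bonds).

    Needs full-atom input (SG side-chain atoms present); useful for
    validating Cys-triad keys, as disulfide bridges pin Cys pairs at a
    characteristic separation.
    """
    sgs = [
        (pos, coord) for pos, name, coord in structure.sidechain_atoms if name == "SG"
    ]
    out = []
    for (p1, c1), (p2, c2) in itertools.combinations(sgs, 2):
        d = float(np.linalg.norm(c1 - c2))
        if d < threshold:
            out.append((p1, p2, d))
    return out
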