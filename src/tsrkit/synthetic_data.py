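"""Deterministic protein-like fixtures with planted triangles.

Structures are Cα chains with exact 3.8 Å consecutive spacing and a
3.0 Å self-avoidance floor, built from three kinds of pieces:

* *planted triangles* — three residues with caller-chosen codes whose
  realized (MaxDist, Theta) equal the requested targets exactly (the
  triangle is constructed in closed form and rigidly inserted);
* *coil bridges* — between consecutive anchored residues, intermediate
  Cα are placed on a closed coil around the straight line so that every
  step is exactly 3.8 Å; requiring at least 1.55 Å of net displacement
  per step makes all non-adjacent intra-bridge distances ≥ 3.0 Å by
  construction;
* *biased random-walk tails* with rejection sampling against clashes.

A planted triple may also emulate a Zn²⁺ site: a ZN HETATM is placed
above the triangle plane and each vertex receives a side-chain ligand
atom 2.1 Å from the ZN, so the motif module classifies it as a binding
site.

Hierarchy datasets plant one class-specific motif per class (plus
optional shared motifs) on a background drawn from a small residue
alphabet that never includes the motif residue types; specificity of
the planted keys is therefore structural, not statistical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretization import (
    MAXDIST_BIN_COUNT,
    THETA_BIN_COUNT,
    BinBoundaries,
    fit_bins,
)
from .key_analysis import HierarchyDataset, HierarchyEntry
from .keys import KeyVector, key_vector, pooled_geometry, structure_triangles
from .labeling import LabelScheme, build_label_scheme
from .structure_io import CalphaStructure, Residue, write_calpha_pdb

__all__ = [
    "PlantedTriple",
    "SyntheticSpec",
    "InfeasibleGeometryError",
    "generate_structure",
    "generate_hierarchy",
    "HierarchyResult",
    "find_triangle_key",
]

STEP = 3.8           # Å, consecutive Cα spacing
MIN_SEPARATION = 3.0  # Å, self-avoidance floor
_MIN_STRETCH = 1.55   # Å net displacement per bridge step (self-avoidance proof)
_MAX_STRETCH = 3.70
ZN_LIGAND_DISTANCE = 2.1  # Å, planted ligand-atom → Zn distance

_LIGAND_FOR = {"HIS": "NE2", "GLU": "OE1", "ASP": "OD1", "CYS": "SG"}

#: default background alphabet for hierarchy datasets (small on purpose:
#: it saturates the background key space in every member)
BACKGROUND_COMPOSITION = {"ALA": 1.0, "GLY": 1.0, "SER": 1.0}

#: residue types reserved for planted class motifs (never in background)
MOTIF_RESIDUES = ("CYS", "HIS", "TRP", "TYR", "MET", "PRO")


class InfeasibleGeometryError(ValueError):
    """Requested planted geometry cannot be embedded in the chain."""


@dataclass(frozen=True)
class PlantedTriple:
    """A triangle to plant: residue codes, chain positions and geometry.

    ``max_dist`` and ``theta`` are the targets for the key pipeline's
    MaxDist (Å) and Theta (degrees, ≤ 90); ``d3_fraction`` fixes the
    midpoint–li3 distance as a fraction of MaxDist.  ``zn_site`` adds a
    ZN record plus ligand atoms turning the triple into a Zn²⁺ site.
    """

    codes: tuple[str, str, str]
    positions: tuple[int, int, int]
    max_dist: float = 8.0
    theta: float = 50.0
    d3_fraction: float = 0.5
    zn_site: bool = False


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic structure."""

    n_residues: int
    seed: int
    planted: tuple[PlantedTriple, ...] = ()
    composition: dict[str, float] | None = None
    structure_id: str = "synthetic"
    chain_id: str = "A"


def _unit(v):
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _triangle_vertices(pt: PlantedTriple, scheme: LabelScheme) -> dict[int, np.ndarray]:
    """Local coordinates of the planted triangle, keyed by chain position.

    The triangle is built in a role frame — li1 at the origin, li2 at
    (D, 0, 0), li3 above the midpoint at distance d3 and angle theta —
    and vertices are matched to chain positions so that bridge
    feasibility (per-step stretch bounds) holds for both chain gaps.
    """
    d = float(pt.max_dist)
    t = np.radians(float(pt.theta))
    if not 0.0 < pt.theta <= 90.0:
        raise InfeasibleGeometryError(f"theta target {pt.theta} outside (0, 90]")
    f = float(pt.d3_fraction)
    v = {
        0: np.array([0.0, 0.0, 0.0]),
        1: np.array([d, 0.0, 0.0]),
        2: np.array([d / 2 + f * d * np.cos(t), f * d * np.sin(t), 0.0]),
    }
    sides = {
        (a, b): float(np.linalg.norm(v[a] - v[b]))
        for a, b in itertools.combinations(range(3), 2)
    }
    if max(sides.values()) > d + 1e-9:
        raise InfeasibleGeometryError(
            f"d3_fraction {f} makes an edge exceed the MaxDist target {d}"
        )
    if min(sides.values()) < MIN_SEPARATION:
        raise InfeasibleGeometryError(
            f"target geometry (D={d}, theta={pt.theta}) puts two vertices "
            f"{min(sides.values()):.2f} Å apart (< {MIN_SEPARATION} Å); "
            "increase MaxDist or theta"
        )

    labels = scheme.labels_for(pt.codes)
    role_labels = np.sort(labels)[::-1]
    order = np.argsort(pt.positions)
    sorted_pos = [pt.positions[i] for i in order]
    sorted_labels = labels[order]

    for perm in itertools.permutations(range(3)):
        # perm[i]: role vertex assigned to the i-th chain position
        if any(sorted_labels[i] != role_labels[perm[i]] for i in range(3)):
            continue
        ok = True
        for a, b in ((0, 1), (1, 2)):
            steps = sorted_pos[b] - sorted_pos[a]
            dist = sides[tuple(sorted((perm[a], perm[b])))]
            if steps == 1:
                ok = STEP - 0.2 <= dist <= STEP + 0.2
            else:
                ok = _MIN_STRETCH * steps <= dist <= _MAX_STRETCH * steps
            if not ok:
                break
        if ok:
            return {sorted_pos[i]: v[perm[i]] for i in range(3)}
    raise InfeasibleGeometryError(
        f"no vertex arrangement of {pt.codes} at positions {pt.positions} "
        "satisfies the chain-spacing constraints; adjust the position gaps"
    )


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _bridge(a, b, n_steps, rng) -> list[np.ndarray]:
    """Intermediate points from a to b: n_steps segments of exactly STEP Å.

    Points lie on a closed coil around the a→b line; every non-adjacent
    pair is ≥ 2 · net-displacement-per-step ≥ 3.1 Å apart.
    """
    length = float(np.linalg.norm(b - a))
    if n_steps == 1:
        if abs(length - STEP) > 0.2:
            raise InfeasibleGeometryError(
                f"adjacent anchors {length:.2f} Å apart cannot be joined by one step"
            )
        return []
    if not _MIN_STRETCH * n_steps <= length <= _MAX_STRETCH * n_steps:
        raise InfeasibleGeometryError(
            f"anchors {length:.2f} Å apart cannot be bridged in {n_steps} steps"
        )
    axis = _unit(b - a)
    per_step = length / n_steps
    c = np.sqrt(STEP**2 - per_step**2)
    rho = c / (2 * np.sin(np.pi / n_steps))
    # orthonormal frame perpendicular to the axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(axis, ref))
    w = np.cross(axis, u)
    phase = rng.uniform(0, 2 * np.pi)
    pts = []
    for tstep in range(1, n_steps):
        ang = 2 * np.pi * tstep / n_steps + phase
        offset = rho * (
            (np.cos(ang) - np.cos(phase)) * u + (np.sin(ang) - np.sin(phase)) * w
        )
        pts.append(a + tstep * per_step * axis + offset)
    return pts


def _walk_step(prev, direction, existing, rng, max_tries=200):
    for _ in range(max_tries):
        cand_dir = _unit(direction + 0.9 * rng.normal(size=3))
        cand = prev + STEP * cand_dir
        if existing.size == 0 or np.min(np.linalg.norm(existing - cand, axis=1)) >= MIN_SEPARATION:
            return cand, cand_dir
    raise InfeasibleGeometryError("random-walk tail could not avoid clashes")


def _assemble_coords(spec: SyntheticSpec, scheme: LabelScheme, rng):
    n = spec.n_residues
    planted = sorted(spec.planted, key=lambda p: min(p.positions))
    used: set[int] = set()
    for pt in planted:
        if len(set(pt.positions)) != 3:
            raise ValueError(f"planted positions {pt.positions} are not distinct")
        if min(pt.positions) < 1 or max(pt.positions) > n:
            raise ValueError(f"planted positions {pt.positions} outside 1..{n}")
        if used & set(pt.positions):
            raise ValueError("planted triples share a chain position")
        used |= set(pt.positions)

    coords = np.full((n, 3), np.nan)
    anchor_idx: list[int] = []
    prev_anchor = None  # (index, coord)
    for pt in planted:
        local = _triangle_vertices(pt, scheme)
        first_pos = min(local)
        rot = _random_rotation(rng)
        placed = {p: (rot @ c) for p, c in local.items()}
        if prev_anchor is None:
            shift = -placed[first_pos]
        else:
            prev_i, prev_c = prev_anchor
            steps = (first_pos - 1) - prev_i
            if steps < 1:
                raise InfeasibleGeometryError("planted triples too close along the chain")
            direction = _unit(np.array([1.0, 0.0, 0.0]) + 0.2 * rng.normal(size=3))
            target = prev_c + (2.6 * steps) * direction
            shift = target - placed[first_pos]
        for p, c in placed.items():
            coords[p - 1] = c + shift
            anchor_idx.append(p - 1)
        prev_anchor = (max(local) - 1, coords[max(local) - 1])
    anchor_idx.sort()

    if not anchor_idx:
        coords[0] = np.zeros(3)
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(1, n):
            coords[i], direction = _walk_step(
                coords[i - 1], direction, coords[:i][~np.isnan(coords[:i, 0])], rng
            )
        return coords

    # bridges between consecutive anchors
    for a, b in zip(anchor_idx, anchor_idx[1:]):
        if b - a == 1 or not np.isnan(coords[a + 1 : b, 0]).all():
            if b - a == 1:
                gap = float(np.linalg.norm(coords[b] - coords[a]))
                if abs(gap - STEP) > 0.2:
                    raise InfeasibleGeometryError(
                        f"adjacent planted residues {a + 1},{b + 1} are {gap:.2f} Å apart"
                    )
            continue
        for k, c in enumerate(_bridge(coords[a], coords[b], b - a, rng), start=1):
            coords[a + k] = c

    # leading tail (built backwards from the first anchor)
    first = anchor_idx[0]
    direction = _unit(coords[first] - coords[first + 1]) if first + 1 < n and not np.isnan(coords[first + 1, 0]).all() else np.array([-1.0, 0.0, 0.0])
    for i in range(first - 1, -1, -1):
        known = coords[~np.isnan(coords[:, 0])]
        coords[i], direction = _walk_step(coords[i + 1], direction, known, rng)
    # trailing tail
    last = anchor_idx[-1]
    direction = _unit(coords[last] - coords[last - 1]) if last > 0 else np.array([1.0, 0.0, 0.0])
    for i in range(last + 1, n):
        if not np.isnan(coords[i, 0]):
            continue
        known = coords[~np.isnan(coords[:, 0])]
        coords[i], direction = _walk_step(coords[i - 1], direction, known, rng)
    return coords


def _validate_chain(coords):
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(np.abs(steps - STEP) > 0.2):
        return False
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    n = len(coords)
    mask = ~np.eye(n, dtype=bool)
    off = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) >= 2
    return bool(np.all(dist[mask & off] >= MIN_SEPARATION - 1e-9))


def generate_structure(spec: SyntheticSpec):
    """Build one synthetic structure; returns (CalphaStructure, pdb_text).

    Deterministic for a fixed spec (same seed → byte-identical PDB).
    """
    if spec.n_residues < 3:
        raise ValueError("need at least 3 residues")
    scheme = build_label_scheme(grouping=False)
    for pt in spec.planted:  # deterministic feasibility checks up front
        if min(pt.positions) < 1 or max(pt.positions) > spec.n_residues:
            raise ValueError(
                f"planted positions {pt.positions} outside 1..{spec.n_residues}"
            )
        _triangle_vertices(pt, scheme)
    master = np.random.default_rng(spec.seed)
    coords = None
    last_error = None
    for _attempt in range(60):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        try:
            cand = _assemble_coords(spec, scheme, rng)
        except InfeasibleGeometryError as err:
            last_error = err
            continue
        if _validate_chain(cand):
            coords = cand
            break
    if coords is None:
        raise last_error or InfeasibleGeometryError(
            f"could not assemble a clash-free chain for {spec.structure_id}"
        )

    composition = spec.composition or {aa: 1.0 for aa in
                                       ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN",
                                        "GLU", "GLY", "HIS", "ILE", "LEU", "LYS",
                                        "MET", "PHE", "PRO", "SER", "THR", "TRP",
                                        "TYR", "VAL")}
    codes = sorted(composition)
    probs = np.array([composition[c] for c in codes], dtype=float)
    probs /= probs.sum()
    seq_rng = np.random.default_rng(spec.seed + 1)
    sequence = list(np.array(codes)[seq_rng.choice(len(codes), size=spec.n_residues, p=probs)])
    for pt in spec.planted:
        for code, pos in zip(pt.codes, pt.positions):
            sequence[pos - 1] = code

    structure = CalphaStructure(structure_id=spec.structure_id, chain_id=spec.chain_id)
    structure.residues = [
        Residue(i + 1, "", sequence[i], coords[i].copy()) for i in range(spec.n_residues)
    ]
    for pt in spec.planted:
        tri = np.array([coords[p - 1] for p in pt.positions])
        centroid = tri.mean(axis=0)
        normal = _unit(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        zn = centroid + 2.0 * normal
        if pt.zn_site:
            structure.hetero_metals.append(("ZN", zn))
        for code, pos in zip(pt.codes, pt.positions):
            atom_name = _LIGAND_FOR.get(code)
            if atom_name is None:
                if pt.zn_site:
                    raise ValueError(f"cannot plant a Zn ligand atom for residue {code}")
                continue
            if pt.zn_site:
                # ligand atom on the Zn side, at bonding distance
                ligand = zn + ZN_LIGAND_DISTANCE * _unit(coords[pos - 1] - zn)
            else:
                # plausible side-chain atom pointing away from the triangle
                ligand = coords[pos - 1] + 1.5 * _unit(coords[pos - 1] - centroid)
            structure.sidechain_atoms.append((pos, atom_name, ligand))
    return structure, write_calpha_pdb(structure)


def find_triangle_key(frame: pd.DataFrame, positions) -> int:
    """Key of the triangle whose vertex positions equal ``positions``."""
    want = set(positions)
    sub = frame[
        frame[["res_i", "res_j", "res_k"]].apply(lambda r: set(r) == want, axis=1)
    ]
    if len(sub) != 1:
        raise ValueError(f"expected exactly one triangle at {sorted(want)}, got {len(sub)}")
    return int(sub["key"].iloc[0])


@dataclass
class HierarchyResult:
    """A generated two-level dataset plus everything needed to audit it."""

    dataset: HierarchyDataset
    structures: dict[str, CalphaStructure]
    scheme: LabelScheme
    theta_bins: BinBoundaries
    maxdist_bins: BinBoundaries
    planted_keys: dict[str, int]          # class name -> planted specific key
    shared_keys: tuple[int, ...] = ()

    @property
    def key_vectors(self) -> dict[str, KeyVector]:
        return {e.structure_id: e.key_vector for e in self.dataset.entries}


def _default_class_motif(index: int) -> PlantedTriple:
    aa = MOTIF_RESIDUES[index % len(MOTIF_RESIDUES)]
    return PlantedTriple(
        codes=(aa, aa, aa),
        positions=(30, 32, 35),
        max_dist=7.5 + 0.5 * index,
        theta=48.0 + 6.0 * index,
    )


def generate_hierarchy(
    n_classes: int = 3,
    n_per_class: int = 4,
    class_specific_motifs=None,
    shared_motifs=(),
    seed: int = 0,
    n_residues: int = 120,
    scheme: LabelScheme | None = None,
    theta_bin_count: int = THETA_BIN_COUNT,
    dist_bin_count: int = MAXDIST_BIN_COUNT,
    composition: dict[str, float] | None = None,
    out_dir=None,
) -> HierarchyResult:
    """Generate a two-level hierarchy dataset with planted motifs.

    Every member of class *i* carries that class's planted motif; shared
    motifs appear in all members of all classes.  Backgrounds are
    independent draws from ``composition`` (default: the small
    Ala/Gly/Ser alphabet).  Bin boundaries are fitted on the pooled
    triangle geometry of the whole dataset, then key vectors and the
    realized planted/shared keys are computed.
    """
    if n_classes < 1 or n_per_class < 1:
        raise ValueError("sizes must be >= 1")
    scheme = scheme or build_label_scheme(grouping=True)
    if class_specific_motifs is None:
        class_specific_motifs = [_default_class_motif(i) for i in range(n_classes)]
    if len(class_specific_motifs) != n_classes:
        raise ValueError("need one class motif per class")
    shared_motifs = tuple(shared_motifs)
    composition = composition or dict(BACKGROUND_COMPOSITION)

    structures: dict[str, CalphaStructure] = {}
    membership: list[tuple[str, str, str]] = []  # (structure_id, class, group)
    for ci in range(n_classes):
        for mi in range(n_per_class):
            sid = f"C{ci + 1}M{mi + 1}"
            spec = SyntheticSpec(
                n_residues=n_residues,
                seed=(seed * 1009 + ci * 101 + mi) % (2**31 - 1),
                planted=(class_specific_motifs[ci],) + shared_motifs,
                composition=composition,
                structure_id=sid,
            )
            structure, pdb_text = generate_structure(spec)
            structures[sid] = structure
            membership.append((sid, f"class{ci + 1}", f"group{ci + 1}"))
            if out_dir is not None:
                with open(f"{out_dir}/{sid}.pdb", "w") as fh:
                    fh.write(pdb_text)

    ordered = [structures[sid] for sid, _, _ in membership]
    maxdist_values, theta_values = pooled_geometry(ordered, scheme)
    maxdist_bins = fit_bins(maxdist_values, dist_bin_count, variable="maxdist")
    theta_bins = fit_bins(theta_values, theta_bin_count, variable="theta")

    entries = []
    for sid, level1, level2 in membership:
        kv = key_vector(structures[sid], scheme, theta_bins, maxdist_bins)
        entries.append(HierarchyEntry(sid, "A", level1, level2, kv))
    dataset = HierarchyDataset(entries=entries)

    planted_keys: dict[str, int] = {}
    shared_keys: list[int] = []
    first_frame = structure_triangles(ordered[0], scheme, theta_bins, maxdist_bins)
    for ci in range(n_classes):
        sid = f"C{ci + 1}M1"
        frame = (
            first_frame
            if sid == ordered[0].structure_id
            else structure_triangles(structures[sid], scheme, theta_bins, maxdist_bins)
        )
        planted_keys[f"class{ci + 1}"] = find_triangle_key(
            frame, class_specific_motifs[ci].positions
        )
    for sm in shared_motifs:
        shared_keys.append(find_triangle_key(first_frame, sm.positions))

    if out_dir is not None:
        manifest = dataset.to_manifest()
        manifest["pdb_path"] = [f"{sid}.pdb" for sid, _, _ in membership]
        manifest.to_csv(f"{out_dir}/manifest.csv", index=False)

    return HierarchyResult(
        dataset=dataset,
        structures=structures,
        scheme=scheme,
        theta_bins=theta_bins,
        maxdist_bins=maxdist_bins,
        planted_keys=planted_keys,
        shared_keys=tuple(shared_keys),
    )
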