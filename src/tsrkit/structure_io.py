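"""PDB parsing into Cα-level structures, plus PDB/FASTA export.

Only the information the key pipeline and the Zn-site screen need is
retained: one Cα per residue of the requested chain, metal HETATM
records, and the side-chain atoms that can ligate a Zn²⁺ ion
(His ND1/NE2, Glu OE1/OE2, Asp OD1/OD2) plus Cys SG for disulfide
reporting.  Format handling is delegated to gemmi; this module applies
the package's parsing policy on top:

* first MODEL only;
* one altloc per residue — highest occupancy, ties broken by the
  lexicographically first altloc identifier;
* MSE mapped to MET; all other non-standard residues excluded from the
  Cα chain (counted in the parse report); metals kept separately;
* residues ordered by sequence number (stable for insertion codes), so
  parsing is insensitive to record order;
* residues without a Cα atom are omitted and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .labeling import AA_THREE_TO_ONE, STANDARD_AMINO_ACIDS

__all__ = [
    "ParseConfig",
    "ParseReport",
    "Residue",
    "CalphaStructure",
    "read_calpha_structure",
    "write_calpha_pdb",
    "extract_sequence",
    "write_fasta",
]

#: side-chain atoms retained for Zn-ligation and disulfide checks
LIGAND_ATOM_NAMES = frozenset({"ND1", "NE2", "OE1", "OE2", "OD1", "OD2", "SG"})

_METALS = frozenset({"ZN", "FE", "MG", "MN", "CU", "NI", "CO", "NA", "K", "CA", "CD", "HG"})


@dataclass(frozen=True)
class ParseConfig:
    """Parsing policy knobs (defaults follow the package conventions)."""

    altloc_policy: str = "highest_occupancy"  # or "first"
    mse_to_met: bool = True


@dataclass
class ParseReport:
    """Counts of records the parsing policy dropped or collapsed."""

    malformed_lines: int = 0
    missing_ca: int = 0
    nonstandard_skipped: int = 0
    duplicate_residues: int = 0
    altloc_collapsed: int = 0

    def log_lines(self, structure_id: str, chain_id: str) -> list[str]:
        prefix = f"{structure_id}/{chain_id}:"
        return [
            f"{prefix} {self.malformed_lines} malformed coordinate line(s) skipped",
            f"{prefix} {self.missing_ca} residue(s) without a C-alpha atom omitted",
            f"{prefix} {self.nonstandard_skipped} non-standard residue(s) excluded",
            f"{prefix} {self.duplicate_residues} duplicate residue record(s) ignored",
            f"{prefix} {self.altloc_collapsed} residue(s) with alternate locations collapsed",
        ]

    @property
    def clean(self) -> bool:
        return not any(
            (self.malformed_lines, self.missing_ca, self.nonstandard_skipped,
             self.duplicate_residues, self.altloc_collapsed)
        )


@dataclass
class Residue:
    seq_position: int
    insertion_code: str
    aa_code: str
    coord: np.ndarray


@dataclass
class CalphaStructure:
    """One chain's ordered Cα residues plus metal/side-chain extras."""

    structure_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    hetero_metals: list[tuple[str, np.ndarray]] = field(default_factory=list)
    sidechain_atoms: list[tuple[int, str, np.ndarray]] = field(default_factory=list)
    parse_report: ParseReport = field(default_factory=ParseReport)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.residues], dtype=float).reshape(-1, 3)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.seq_position for r in self.residues], dtype=np.int64)

    @property
    def aa_codes(self) -> list[str]:
        return [r.aa_code for r in self.residues]

    def transformed(self, rotation=None, translation=None) -> "CalphaStructure":
        """Rigid-body transformed copy (rotation applied before translation)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        tr = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        out = CalphaStructure(self.structure_id, self.chain_id)
        out.residues = [
            Residue(r.seq_position, r.insertion_code, r.aa_code, r.coord @ rot.T + tr)
            for r in self.residues
        ]
        out.hetero_metals = [(e, c @ rot.T + tr) for e, c in self.hetero_metals]
        out.sidechain_atoms = [(p, n, c @ rot.T + tr) for p, n, c in self.sidechain_atoms]
        return out


def _prefilter(pdb_text: str):
    """Drop coordinate lines too short to hold x,y,z; count them."""
    kept, malformed = [], 0
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM") and len(line.rstrip("\n")) < 54:
            malformed += 1
            continue
        kept.append(line)
    return "\n".join(kept) + "\n", malformed


def _pick_altloc(atoms, policy: str):
    """Select one atom among altloc copies of the same atom name."""
    if len(atoms) == 1:
        return atoms[0], 0
    if policy == "first":
        return atoms[0], 1
    chosen = sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]
    return chosen, 1


def read_calpha_structure(pdb_text: str, chain_id: str,
                          config: ParseConfig = ParseConfig(),
                          structure_id: str = "structure") -> CalphaStructure:
    """Parse PDB-format text into a :class:`CalphaStructure` for one chain."""
    text, malformed = _prefilter(pdb_text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError(f"{structure_id}: no model found in PDB text")
    model = st[0]  # first MODEL only

    report = ParseReport(malformed_lines=malformed)
    records: list[Residue] = []
    sidechains: list[tuple[int, str, np.ndarray]] = []
    metals: list[tuple[str, np.ndarray]] = []
    seen: set[tuple[int, str]] = set()

    for chain in model:
        for res in chain:
            atoms = list(res)
            # metal HETATM records are collected from every chain
            if (res.het_flag == "H" and len(atoms) == 1
                    and atoms[0].element.name.upper() in _METALS
                    and res.name.upper() == atoms[0].name.strip().upper()):
                pos = atoms[0].pos
                metals.append((atoms[0].element.name.upper(),
                               np.array([pos.x, pos.y, pos.z])))
                continue
            if chain.name != chain_id:
                continue
            aa = res.name.upper()
            if aa == "MSE" and config.mse_to_met:
                aa = "MET"
            if aa not in STANDARD_AMINO_ACIDS:
                report.nonstandard_skipped += 1
                continue
            identity = (res.seqid.num, res.seqid.icode.strip())
            if identity in seen:
                report.duplicate_residues += 1
                continue
            ca_copies = [a for a in atoms if a.name == "CA"]
            if not ca_copies:
                report.missing_ca += 1
                continue
            seen.add(identity)
            ca, collapsed = _pick_altloc(ca_copies, config.altloc_policy)
            report.altloc_collapsed += collapsed
            records.append(
                Residue(res.seqid.num, identity[1], aa,
                        np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
            )
            by_name: dict[str, list] = {}
            for a in atoms:
                if a.name in LIGAND_ATOM_NAMES:
                    by_name.setdefault(a.name, []).append(a)
            for name, copies in by_name.items():
                atom, _ = _pick_altloc(copies, config.altloc_policy)
                sidechains.append(
                    (res.seqid.num, name,
                     np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                )

    if not records:
        raise ValueError(
            f"no C-alpha atoms found for chain '{chain_id}' of {structure_id}"
        )
    records.sort(key=lambda r: r.seq_position)  # stable: keeps icode file order
    return CalphaStructure(
        structure_id=structure_id,
        chain_id=chain_id,
        residues=records,
        hetero_metals=metals,
        sidechain_atoms=sidechains,
        parse_report=report,
    )


def write_calpha_pdb(structure: CalphaStructure) -> str:
    """Serialize a :class:`CalphaStructure` to PDB-format text.

    Writes one CA ATOM per residue (plus any stored side-chain atoms)
    and each metal as a single-atom HETATM residue in chain 'Z'.
    Coordinates are written at the format's 3-decimal precision.
    """
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(structure.chain_id)
    side_by_pos: dict[int, list[tuple[str, np.ndarray]]] = {}
    for pos, name, coord in structure.sidechain_atoms:
        side_by_pos.setdefault(pos, []).append((name, coord))
    for r in structure.residues:
        res = gemmi.Residue()
        res.name = r.aa_code
        res.seqid = gemmi.SeqId(r.seq_position, r.insertion_code or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        atom.pos = gemmi.Position(*r.coord)
        res.add_atom(atom)
        for name, coord in side_by_pos.get(r.seq_position, []):
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(name[0])
            a.occ = 1.0
            a.pos = gemmi.Position(*coord)
            res.add_atom(a)
        chain.add_residue(res)
    model.add_chain(chain)
    if structure.hetero_metals:
        met_chain = gemmi.Chain("Z")
        for i, (element, coord) in enumerate(structure.hetero_metals, 1):
            res = gemmi.Residue()
            res.name = element
            res.seqid = gemmi.SeqId(9000 + i, " ")
            res.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = element
            atom.element = gemmi.Element(element.capitalize())
            atom.occ = 1.0
            atom.pos = gemmi.Position(*coord)
            res.add_atom(atom)
            met_chain.add_residue(res)
        model.add_chain(met_chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def extract_sequence(structure: CalphaStructure) -> str:
    """One-letter amino-acid string in residue order."""
    return "".join(AA_THREE_TO_ONE[r.aa_code] for r in structure.residues)


def write_fasta(structures, path) -> None:
    """Export extracted sequences of one or more structures as FASTA."""
    records = [
        SeqRecord(Seq(extract_sequence(s)),
                  id=f"{s.structure_id}_{s.chain_id}", description="")
        for s in structures
    ]
    SeqIO.write(records, path, "fasta")
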