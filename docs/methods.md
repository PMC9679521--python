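# Methods

This note records the model implemented by `tsrkit`, the numerical and
design choices made where the method family leaves them open, what the
synthetic-data generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Triangle descriptors

For a triangle of Cα atoms with role-ordered vertices (li1, li2, li3):
d12 = |li1−li2|, d13 = |li1−li3|, d3 = distance from the li1–li2
midpoint to li3. The angle representative is

    θ1 = arccos( (d13² − (d12/2)² − d3²) / (2·(d12/2)·d3) ),
    θΔ = θ1            if θ1 ≤ 90°
         180° − θ1     otherwise.

By Apollonius' median relation, swapping the li1/li2 roles negates the
arccos argument, so the fold into [0°, 90°] makes θΔ independent of
that sign convention (this is tested as a property). θ1 exactly 90°
takes the ≤ 90° branch. The length representative MaxDist is the
largest of the three edge lengths. Degenerate triangles — coincident
vertices, d3 = 0, or an arccos argument beyond ±1 by more than 1e-9 —
have no defined angle; they are excluded from key vectors and counted,
never clamped into a bin. Arguments within 1e-9 of ±1 are clamped.

## Vertex roles and label schemes

Roles are assigned by sorting vertex labels in descending order. Ties
are broken by canonical residue precedence (the 20-letter labels), then
by maximizing d12, then d13, then by the lowest sequence position in
the li1 role. The rule uses coordinates only through pairwise
distances, hence is rigid-body invariant; it is also invariant to the
order in which vertices are supplied.

The per-amino-acid integers are not fully determined by the published
key integers; decoding the printed keys fixes Cys=5, Leu=8, His=9,
Arg=22 in the ungrouped scheme (labels 4..23) and Cys=13, Gly=6 in the
grouped scheme (labels 1..13). The remaining default assignments are
this package's choice, made so that the two schemes rank amino acids
*consistently* wherever those anchors allow: merged pairs occupy
adjacent ungrouped labels, and the grouped category order follows the
ungrouped order for every pair of residues except Cys (see
Limitations). Both tables can be replaced by a two-column mapping file;
validation enforces 20 (or 13) contiguous labels, a range width ≤ m
(the condition that makes the key encoding injective), and under
grouping exactly the seven merged pairs Ser/Thr, Ala/Val, Leu/Ile,
Phe/Trp, Asp/Glu, Asn/Gln, Lys/Arg.

## Key encoding

k = θT·dT·[(li1−1)m² + (li2−1)m + (li3−1)] + θT·(d−1) + (θ−1), with
θT = 29, dT = 35 by default, evaluated in exact integer arithmetic
(maximum grouped key ≈ 2.3M, ungrouped ≈ 9.4M; far below 2⁶³). The
mixed-radix digits (li−1) may exceed m−1 (ungrouped labels are 4..23
with m = 20), but because each scheme's label-range width is at most m,
every digit position contains exactly one admissible value per residue
class modulo m, so decoding is unique. `decompose_key` implements this
digit recovery and rejects keys with no admissible preimage. The test
suite enumerates the full grouped space (13³·35·29 ≈ 2.23M encodings)
and verifies zero collisions and an exact round trip on every
admissible (descending-label) tuple.

## Discretization

Bin boundaries for MaxDist and Theta are fitted per dataset by adaptive
equal-frequency binning: cuts may only fall between distinct sorted
values (all occurrences of the same value share a bin), and the
objective is the minimax deviation max_b |pop_b − N/B|. For up to 512
distinct values the optimum is found exactly by dynamic programming
over contiguous partitions; above that, greedy quantile cuts are
refined by a deterministic local search (moving one cut at a time while
the objective improves, up to 200 passes). Interval convention: bins
are half-open [bᵢ, bᵢ₊₁) with the last bin closed; values outside the
fitted range are clamped to the outer bins with a warning. Fixed
boundary tables can be written/read as plain text and injected in place
of fitting, which is required to reproduce key integers generated with
any previously published binning.

MaxDist and Theta are rounded to 1e-6 (Å, degrees) before binning.
Rigid transforms perturb recomputed distances at the 1e-13 level; the
rounding collapses such copies to bit-identical values so the
same-value-same-bin guarantee covers them, making key vectors exactly
rigid-body invariant in practice.

## Similarity, clustering, mining

Generalized Jaccard over key multisets (Σ min / Σ max), distance
1 − similarity, average-linkage (UPGMA) clustering via
`scipy.cluster.hierarchy.linkage` with scipy's deterministic tie
handling; dendrograms export as Newick through scikit-bio. The summary
similarity of a set defaults to the unweighted mean over unordered
pairs, with optional per-structure weights (product weighting per
pair).

Common keys of a set of structures are the intersection of their
distinct-key sets; the weighted variant carries each common key's
minimum occurrence frequency. The common-key percentage is
100·|common| / |union| reported to one decimal. Specific keys of a
hierarchy node are the keys supported by at least `min_support`
(default 1.0) of the node's members and absent from every outside
structure. Venn region counts treat a key as belonging to a class if
any member contains it (union scale) and are computed for 2–5 classes.

## Zn²⁺ site screening

All {His, His, Glu-or-Asp} residue triples become motif triangles with
the same Cα geometry as the key pipeline (side chains are never used
for geometry). A triangle is a site when all three residues have a
side-chain ligand atom (His ND1/NE2, Glu OE1/OE2, Asp OD1/OD2) within
3.0 Å of the same ZN record — Zn–N/O coordination bonds are typically
2.0–2.3 Å, so 3.0 Å gives margin without reaching second-shell atoms.
For apo structures (no ZN) a user-supplied annotation list of site
triples decides; with neither, the triangle is reported "unassigned".
The HExxH scan reports all 1-based match positions including overlaps.
A disulfide report (SG–SG pairs below 2.20 Å) supports validating
Cys-triad keys on full-atom inputs.

## PDB parsing policy

gemmi handles the format. Policy on top: first MODEL only; one altloc
per residue (highest occupancy, ties to the lexicographically first
altloc identifier); MSE→MET, all other non-standard residues excluded
from the Cα chain; metals kept separately from any chain; residues
ordered by sequence number with a stable sort (so record order within a
chain is irrelevant and insertion-code duplicates keep file order);
residues without a Cα are omitted. Every dropped or collapsed record is
counted in a parse report. Coordinate lines too short to carry x,y,z
are skipped and counted before gemmi sees them.

## Synthetic data generator

Structures are Cα chains with exact 3.8 Å consecutive spacing and a
3.0 Å self-avoidance floor. Planted triangles are constructed in closed
form — li1 at the origin, li2 at (D, 0, 0), li3 above the li1–li2
midpoint at distance `d3_fraction`·D (default 0.5) and angle θ — so the
realized MaxDist and Theta equal their targets to float precision, then
rigidly inserted with a random orientation. Chain segments between
anchored residues are closed coils around the straight line whose every
chord is exactly 3.8 Å; requiring ≥ 1.55 Å net displacement per step
makes all intra-bridge non-adjacent distances ≥ 3.0 Å by construction.
Tails are biased self-avoiding random walks. Assembly retries with
fresh substreams (up to 60) until the global spacing and clash checks
pass; everything is driven by one seeded generator, so a fixed spec
yields byte-identical PDB text.

Hierarchy datasets default to 3 classes × 4 members of 120 residues.
The background alphabet is deliberately small (Ala/Gly/Ser, uniform):
with C(120,3) ≈ 281k triangles per structure spread over only ~10
label-combination classes × 1015 geometry cells, nearly every
background key occurs in nearly every member, so a background key
essentially never ends up class-specific by chance. Class motifs use
residue types absent from the background (Cys, His, Trp, ... triads at
class-distinct geometries), which makes the planted key's specificity
structural: no other class can contain it at all. Note that the three
planted residues also form mixed triangles with background residues;
those keys are *genuinely* class-specific too (only that class contains
the residue type) — mirroring how real class-specific keys arise from,
e.g., disulfide-pinned Cys triads — so tests assert that the planted
key is recovered and that no specific key is composed purely of
background labels, not that the specific set is a singleton. Zn-site
planting adds a ZN 2.0 Å above the triangle plane and one ligand atom
per vertex at 2.1 Å from the ZN; non-site planted His/Glu/Asp triples
get plausible far-from-metal ligand atoms so they classify as
non-site rather than unassigned.

What the generator does not emulate: Ramachandran statistics, secondary
structure, realistic amino-acid composition, crystallographic noise,
missing residues. Passing tests therefore demonstrate the
correctness of the pipeline's bookkeeping and invariances on idealized
chains, not retrieval performance on real folds.

## Problem sizes used in the checks

The full-space encode/decode audit covers all ≈2.23M grouped
combinations. Planted-key recovery runs five hierarchy datasets
(seeds 1–5, 12 structures × 281k triangles each). Rigid-body invariance
uses 20 random rigid transforms of a 50-residue structure. These sizes
were chosen so the whole suite runs in a couple of minutes on one CPU
while still exercising every code path at full fidelity.

## Known limitations

* **Cross-scheme Theta agreement.** Vertex roles depend on label order,
  and the published anchor values force Cys to sit low in the ungrouped
  order (5 of 4..23) but at the top of the grouped order (13 of 13). No
  pair of tables satisfying the anchors can therefore rank a mixed
  Cys-containing triangle consistently in both schemes, and for such
  triangles the two schemes may disagree on (d, θ) bins. The default
  tables confine the disagreement to Cys-vs-non-Met pairs; for every
  other composition (and for all label-symmetric triangles, which is
  what the printed grouped/ungrouped key pairs show) the (d, θ) bins
  agree exactly, and the test suite verifies this on datasets free of
  mixed-Cys triangles.
* **Bit-compatibility with previously published key files** requires
  the original boundary tables and the original full label tables;
  both are injectable, but the shipped defaults only guarantee the
  decoded anchors above. Likewise the published per-structure key-set
  occurrence totals (e.g. for chymotrypsin 4H4F) are reproducible only
  with the original structure files and boundary tables supplied; the
  code path that does this (fixed boundaries + key-set totals) is
  tested against an independent brute-force reference on synthetic
  input.
* The exact iterative rule of the original adaptive discretization is
  not public; ours is an exact/greedy minimax equal-frequency
  procedure honoring the same constraints, and is deterministic.
* Enumerating all C(n,3) triangles is O(n³): ~10⁸ triangles for a
  1000-residue chain. The pipeline is vectorized but intended for
  chains up to a few hundred residues per structure.
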