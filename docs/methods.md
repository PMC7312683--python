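# Methods

This note documents the models, conventions and numerical choices behind
`minorgroove`, in the order the pipeline applies them.

## Structure model and dataset filters

Structures are parsed with gemmi (PDB mandatory, mmCIF optional) into a
lightweight chain/residue/atom model. Hydrogens are discarded on parse: every
distance criterion in the pipeline is defined over non-hydrogen atoms.
Alternate locations are collapsed to the highest-occupancy conformer (ties to
the first conformer in file order), and only the first MODEL of a multi-model
file is read — multi-model X-ray depositions are rare, and the pipeline's
filters target crystal structures anyway. Nucleotide naming dialects
(DA/DC/DG/DT, bare A/C/G/T with a deoxyribose, legacy `O1P`/`C5M`/`*` atom
names) are normalized to dA/dC/dG/dT with PDBv3 atom names. Residue identity
is `(chain_id, author seq_id + insertion code)` throughout.

Dataset admissibility mirrors common curation practice: experimental method
on an allow-list (default: X-ray diffraction, plus the synthetic generator's
label so fixture bundles flow through the same code path), resolution at or
better than 3.5 Å (missing resolution metadata excludes the entry, with a
logged reason), and an optional `(structure_id, chain_id)` allow-list applied
to protein chains as a stand-in for sequence-identity-based redundancy
removal, which is out of scope. DNA chains are validated independently: every
residue must be a standard deoxyribonucleotide, no atom HETATM-flagged, and
the full heavy-atom inventory present (the 5′-terminal phosphate group is
optional, matching deposition practice).

## Base pairs, duplexes and the groove-width convention

Watson–Crick pairs are detected geometrically between different chains:
complementary bases, purine N1 to pyrimidine N3 distance ≤ 3.5 Å (the
central WC hydrogen bond), and C1′–C1′ distance in [9.5, 11.5] Å. Candidates
are accepted greedily by increasing N1–N3 distance so each nucleotide pairs at
most once. Maximal runs of sequence-adjacent, antiparallel pairs become
duplexes; runs shorter than 3 bp are discarded. Hairpins (intra-chain
pairing) are not considered.

The minor groove width at dinucleotide step *k* is the minimum **direct**
cross-strand P–P distance among phosphates within ±3.5 base-pair levels of
the step center (a phosphate sits half a level 5′ of its residue), restricted
to pairs whose midpoint is closer to the step's minor-groove reference atoms
than to its major-groove ones. This midpoint test replaces a fixed offset
table and behaves correctly in bent helices, where no global axis exists. No
5.8 Å van der Waals correction is subtracted: the narrow (≤ 11.0 Å) /
standard / wide (≥ 17.0 Å) category bounds are stated on this raw P–P scale,
consistent with an ideal B-form helix measuring ~11.7 Å (standard) and an
ideal A-form helix 18.5 Å (wide). Widths are undefined at terminal steps and
wherever no minor-side phosphate pair exists (at least one flanking base pair
is required on each side, so a 3-bp duplex has no widths and a 5-bp duplex
has them only at its interior steps). Width is invariant under rigid motion
by construction. An importer for externally computed per-step width tables
(plain-text, step index + width columns) lets users substitute another
program's values; unmatched rows are reported.

Sugar puckers use the standard pseudorotation analysis of the five
endocyclic torsions ν0–ν4: phase *P* from tan *P* = (ν4+ν1−ν3−ν0) /
(2ν2(sin 36° + sin 72°)) with the ν2 < 0 quadrant correction, amplitude
τm = ν2 / cos *P*. Labels: C3′-endo for *P* ∈ [0°, 36°), C2′-endo for
[144°, 180°), otherwise *other*; amplitudes below 5° are flagged
near-planar and labelled *other*.

## Contact detection and step assignment

Reference atoms per base: adenine N3/N6, guanine N3/O6, thymine O2/O4,
cytosine O2/N4 (minor/major). For each amino acid residue the distance to a
reference atom is the minimum over the residue's heavy atoms; the search
spans all validated duplexes of the structure, resolving cross-duplex
ambiguity by the global minimum. A residue is retained iff its nearest
reference atom is a minor-groove atom **and** the distance is strictly below
the 6.0 Å cutoff (configurable). Each retained residue gets the dinucleotide
step joining its nearest contacted nucleotide and the same-strand neighbor
whose minor-groove reference atom is closer; a terminal nucleotide uses its
only neighbor, and an exact tie breaks to the 5′ neighbor (deterministic and
orientation-stable). One record per (residue, step); records whose step lacks
a width are dropped with a logged reason. Manual curation is represented
purely as a blacklist input of residue identities — no geometric heuristic
tries to reproduce visual inspection. Family-based pruning consumes a
`(structure, chain, seq) → accession` table and removes records mapping to
excluded families (defaults PF00505, PF00352 — the archetypal wide-groove
binder families); unannotated residues are retained, and pruning is
idempotent.

Step sequences are reported on strand 1, 5′→3′; for reports, complementary
step sequences are pooled into the 10 step classes (ApA/TpT, ApT, TpA,
CpC/GpG, ...), since the minor-groove edge cannot distinguish a step from its
reverse complement.

## Interfaces, hexamer windows, GC content

A protein–DNA interface is a maximal run of contacted steps in which up to 2
consecutive non-contacted steps are bridged. Interfaces spanning ≥ 6
nucleotides are scanned with a 6-nucleotide window at stride 1: the window's
width is its central step's (windows with an undefined central width are
skipped, never imputed — this also answers what happens over bridged gap
nucleotides: they are legitimate window centers, being part of the interface
by definition), its GC content is the count of G/C strand-1 nucleotides over
6 (identical on either strand under WC pairing), and its residue set is the
union of residues contacting any of its five steps. Width distributions are
tabulated at the seven GC levels, pooled and per amino acid (a window enters
an amino acid's table iff that type is among its contacting residues).

## Statistics

Composition distributions are counted over the 20 amino acids per width
category. Relative entropy D(p‖q) = Σ pᵢ log₂(pᵢ/qᵢ) is reported in bits,
with 0·log(0/·) = 0; the *reference* distribution q is smoothed by adding a
pseudocount (default 0.5) to every count before renormalization, keeping D
finite without distorting p. The direction convention is that "narrow to
standard" means D(narrow ‖ standard) — the first-named distribution is p.

The width-shift tests: amino acids split into a hydrophobic group (Leu, Ala,
Ile, Val, Gly, Phe, Trp, Tyr, Met) and a non-hydrophobic group (Asp, His,
Glu, Gln, Asn, Thr, Ser, Lys, Cys, Pro), with arginine excluded outright
from both test and comparison populations (its abundance and narrow-groove
preference would dominate the pooled distributions). Each hydrophobic amino
acid's width sample is compared against the pooled non-hydrophobic widths,
each non-hydrophobic amino acid against the pooled widths of the *other*
non-hydrophobic amino acids; the one-sided alternative is that the first
median is greater. The U statistic uses midranks. The p-value is exact — full
enumeration of all C(n₁+n₂, n₁) labelings of the pooled sample, ties handled
naturally through the fixed midrank multiset — whenever min(n₁, n₂) ≤ 8 and
the number of labelings is ≤ 200 000; otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction. Constant pooled data
is degenerate and reported as p = 1 with a flag. No multiple-testing
correction is applied (per-test 95% level); the number of tests run is
recorded in the output for transparency. Percentile thresholds of the width
multiset use linear interpolation (numpy's default convention). Boxplot
summaries use 1.5·IQR whiskers.

## Secondary structure and interaction modes

φ/ψ are computed from consecutive backbone atoms (termini undefined).
Secondary structure comes from a φ/ψ-region classifier, not from
hydrogen-bond energies — the pipeline stays self-contained and an importer
for classic columnar DSSP output is provided when the original labels are
wanted. Regions (checked in order): α-helix φ ∈ [−100, −30], ψ ∈ [−80, −5];
3₁₀-helix φ ∈ [−90, −40], ψ ∈ (−5, 30]; polyproline-II φ ∈ [−90, −55],
ψ ∈ [120, 180]; β-strand φ ∈ [−170, −70], ψ ∈ [90, 180] ∪ [−180, −170].
Polyproline-II deliberately precedes β-strand where they overlap, since a
dihedral-only classifier cannot use the hydrogen bonding that separates them;
consequently the membership of the residual "others" class differs from
energy-based assignments. Outside every named region, Cα virtual-bond
curvature over a centered 5-residue window assigns bend (> 70°) or turn
(> 45°), else *others*; undefined dihedrals give *unassigned*.

Hydrogen bonds are geometric: donor–acceptor heavy-atom distance ≤ 3.5 Å and
antecedent–donor–acceptor angle ≥ 90°, scanned in both directions between
packaged donor/acceptor tables for the 20 amino acids and the 4 bases. Each
bond is classified by protein side (backbone N/O vs side chain) and DNA
target (base / deoxyribose / phosphate, with O4′ and the sugar carbons as
deoxyribose and OP1/OP2/O5′/O3′/P as phosphate). Van der Waals contacts are
heavy-atom pairs within 4.0 Å not already hydrogen-bonded. All thresholds
are stated constants, configurable at the call sites.

Kabsch superposition solves the proper-rotation least-squares problem by SVD
with a determinant correction; collinear or < 3-point inputs are rejected.
The representative dinucleotide step of a set minimizes the summed pairwise
RMSD over the atoms common to all steps (ties to the lowest index).

## The synthetic generator

The generator emulates what the analysis needs from real crystal structures:
ideal double-helical geometry spanning the three width categories, and
protein residues at controlled reference-atom distances.

Duplexes are built from internal coordinates: standard reference-frame base
geometries (the community-standard idealized base tables; strand 2 by a 180°
rotation about the pair x axis), a deoxyribose ring parametrized by
pseudorotation phase and amplitude, exocyclic atoms from ideal bond
geometry, and rigid placement of each pair on a uniform helix (twist/rise,
x-displacement, inclination about the pair's dyad axis so the two strands
stay symmetric). The per-form conformational constants (χ, γ, β, pucker
phase, x-displacement, inclination) were fixed once by a least-squares
calibration — documented and re-runnable in `scripts/derive_fiber_params.py` —
that (a) selects the sugar chirality giving a chemically correct
β-D-deoxyribose, (b) sets the pucker to C3′-endo (A) / C2′-endo (B), and
(c) closes the inter-residue O3′–P linkage at 1.60 Å on both strands while
reproducing the canonical central-step widths: 18.5 Å for A-form (the ideal
A-DNA anchor) and 11.7 Å for B-form (the direct P–P value of an ideal
B-helix). Helical parameters are 32.7°/2.56 Å (A) and 36.0°/3.38 Å (B) per
step. The model is idealized: no propeller, roll, slide or sequence-dependent
mechanics — uniform geometry is exactly what makes planted ground truth
unambiguous, and it is also what the model does **not** share with real
crystal structures, where grooves are modulated by sequence and packing.
Passing tests on generated structures therefore validate the algorithms'
correctness, not any biological claim about real interfaces.

Groove perturbations apply a Gaussian radial bulge (σ = 4 Å along the helix
axis) to atoms outside the 6 Å base core, widening or narrowing the grooves
smoothly; a guard rejects deformations changing any backbone bond by more
than 0.5 Å. The narrow category is reached from B-form with ≈ −1 Å
displacements; the wide category is natively covered by A-form.

Probe residues are full heavy-atom amino acids (templates from biotite's
chemical component dictionary) placed so the probe's nearest atom sits at
exactly the requested distance from the requested reference atom. The solver
ranks seeded candidate directions in the outward hemisphere around the
groove bisector by the clearance of the future lead-atom position, then
tries principal-axis-aligned orientations with random spins. Margins differ
by groove, reflecting what each planted expectation claims: a minor-groove
probe must have the target atom as its *uniquely* nearest reference atom
(every other reference atom ≥ 0.5 Å farther) because its detection identity
— which nucleotide, which step — is asserted; a major-groove probe only
asserts exclusion by the groove rule, so it requires every minor-groove atom
to trail the nearest major-groove atom by ≥ 0.5 Å (in A-form major grooves,
neighboring major reference atoms cluster within ~3 Å, making unique
nearest-atom margins geometrically unsatisfiable). Probes keep ≥ 2 Å from
all existing heavy atoms. Everything is deterministic for a given seed, and
every planted probe is recorded in the ledger with its expected outcome,
including the expected step index computed by direct arithmetic on the
emitted coordinates.

Peptides with prescribed (φ, ψ) are built by sequential atom placement from
ideal bond lengths and angles (ω = 180°), so target dihedrals are recovered
exactly; these exercise the secondary-structure classifier. Defect mutants
introduce exactly one flaw (missing atom, non-standard residue name, or a
base displaced 20 Å) for negative validation tests.

## Pipeline and reproducibility

Stage order: filters → DNA validation → base pairs → duplexes → widths →
contacts → step assignment → blacklist → table; every drop leaves a reason in
the run manifest and record counts are conserved across stages. All
paper-derived constants (cutoff 6.0 Å, category bounds 11/17 Å, gap limit 2,
excluded families, α = 0.05, entropy pseudocount 0.5) are configuration
defaults, so sensitivity re-runs are one flag away. Runs are deterministic
for a fixed config and seed, down to byte-identical TSV output.

Test-suite problem sizes: the planted-contact battery uses 50 complexes of
12–16 bp with 4 probes each (~200 probes straddling the 6.0 Å cutoff and the
minor/major rule); Mann–Whitney oracle equivalence enumerates all labelings
for 200 seeded sample pairs with n₁+n₂ ≤ 12; the type-I-error check runs
1000 null replicates of the 19-test scheme with 12 widths per amino acid.
These sizes give exact combinatorial answers where exactness is claimed and
binomial standard errors well inside the asserted bands elsewhere.

## Known limitations

- The fiber model is uniform and idealized (see above); it cannot emulate
  sequence-dependent shape, kinks, or intercalation-induced deformations.
- Base-pair detection is purely geometric and WC-only; non-canonical pairs,
  hairpins and intra-chain duplexes are out of scope.
- The φ/ψ secondary-structure classes approximate, but do not reproduce,
  energy-based assignments (notably turn/bend and the "others" residue).
- Hydrogen-bond detection uses heavy-atom geometry only; no hydrogen
  placement, no energy model.
- The groove-width midpoint test assumes reference atoms flag the groove
  sides sensibly; in extremely deformed helices widths may be undefined
  rather than wrong (the minimum-over-window convention degrades by
  reporting no value when no minor-side phosphate pair exists).
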