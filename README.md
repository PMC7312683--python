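# minorgroove

Analysis of protein–DNA **minor groove** interfaces from 3D structures of
protein–DNA complexes.

Proteins read DNA not only through base-specific hydrogen bonds (direct
readout) but also through the local shape of the double helix (indirect
readout). The width of the minor groove is the classic shape descriptor:
narrow minor grooves attract arginines through their focused electrostatic
potential, while widened minor grooves — up to the 18.5 Å of an ideal A-form
helix — are associated with hydrophobic side chains. `minorgroove` implements
the full analysis chain needed to study this association:

- **Contact detection by reference atoms.** Each nucleobase carries one
  reference atom per groove, approximately central in that groove
  (adenine N3/N6, guanine N3/O6, thymine O2/O4, cytosine O2/N4 for
  minor/major respectively). An amino acid residue is *minor-groove-
  contacting* iff its globally nearest reference atom — distance measured
  from any of its non-hydrogen atoms — is a minor-groove atom at < 6.0 Å.
- **Dinucleotide-step association.** Every contacting residue is assigned the
  step formed by the nearest contacted nucleotide and the closer of its two
  same-strand neighbors (closer in minor-groove reference-atom distance;
  ties go 5′).
- **Minor groove width.** For each step, the minimum direct cross-strand
  P–P distance over a local window, restricted to phosphate pairs whose
  midpoint lies on the minor-groove side. No van der Waals subtraction:
  widths live on the raw P–P scale on which the categories
  narrow (≤ 11 Å) / standard / wide (≥ 17 Å) are defined.
- **Statistics.** Per-category amino-acid composition, relative entropy
  (Kullback–Leibler divergence, bits) between category compositions, and a
  one-sided Mann–Whitney *U* scheme testing whether the widths contacted by
  each amino acid are shifted upward relative to the pooled non-hydrophobic
  group (arginine excluded; exact enumeration for small samples, tie- and
  continuity-corrected normal approximation otherwise).
- **Sequence and structure context.** Interface segments (contacted step runs
  bridging gaps ≤ 2), 6-nucleotide sliding windows with central-step width and
  GC content, complement-pooled dinucleotide preferences, φ/ψ-region secondary
  structure, geometric hydrogen-bond and van der Waals interaction modes, and
  Kabsch superposition utilities.
- **A fully ledgered synthetic generator.** Ideal A- and B-form fiber-model
  duplexes built from internal coordinates, groove perturbations, and
  amino-acid probe residues planted at exact reference-atom distances, with a
  ground-truth ledger — so every stage of the pipeline is testable without
  downloading a single structure.

## Worked example

Generate two synthetic complexes (a B-form and an A-form duplex with planted
probe residues), build the contact dataset, and analyze it:

```sh
minorgroove synth spec.yaml --seed 13 --outdir bundle
minorgroove build --inputs 'bundle/*.pdb' --outdir out
minorgroove analyze out/ds1.tsv --structures 'bundle/*.pdb' --outdir reports
```

with `spec.yaml`:

```yaml
complexes:
  - id: DEMO1
    form: B
    sequence: ATGCATGCATGCAT
    probes:
      - {amino_acid: PHE, target_chain: A, target_seq: 7, groove: minor, distance: 5.0}
      - {amino_acid: GLY, target_chain: B, target_seq: 6, groove: minor, distance: 4.5}
      - {amino_acid: LYS, target_chain: A, target_seq: 8, groove: minor, distance: 6.5}
  - id: DEMO2
    form: A
    sequence: GCGCGCGCGCGC
    probes:
      - {amino_acid: ALA, target_chain: A, target_seq: 6, groove: minor, distance: 5.5}
      - {amino_acid: SER, target_chain: B, target_seq: 5, groove: minor, distance: 5.0}
```

`out/ds1.tsv` then contains one row per (residue, step) pair:

```
structure_id  chain  residue_type  residue_seq  nucleotide  step_index  step_sequence  groove  distance_A  width_A  category
DEMO1         P      PHE           1            A:7         5           TG             minor   5.0007      11.6824  standard
DEMO1         P      GLY           2            B:6         8           AT             minor   4.4994      11.6822  standard
DEMO2         P      ALA           1            A:6         4           GC             minor   5.5002      18.4997  wide
DEMO2         P      SER           2            B:5         7           CG             minor   5.0001      18.5001  wide
```

Reading the output: the LYS probe planted at 6.5 Å is absent (the cutoff is a
strict 6.0 Å); the B-form contacts sit in the standard category at the
canonical ~11.7 Å direct P–P width, while the A-form contacts land in the
wide category at 18.5 Å — the hallmark width of an ideal A-form minor groove.
`minorgroove analyze` adds composition tables, relative entropies in bits,
Mann–Whitney width tests, per-amino-acid width boxplot data, sequence
preferences, secondary-structure cross-tabs and interaction-mode tables under
`reports/`.

The same functionality is available as a library
(`minorgroove.contact_detection`, `minorgroove.helix_model`,
`minorgroove.statistics`, ...); the command line is a thin wrapper over
`minorgroove.pipeline_cli.run_build` / `run_analyze` / `run_synth`.

## Scope notes

The package analyzes structures the user supplies. Dataset-level curation
services are out of scope and replaced by explicit inputs: a resolution/
method filter plus an optional chain allow-list stands in for non-redundancy
pipelines, protein-family pruning (`minorgroove prune`, default exclusions
PF00505 and PF00352) consumes a user-provided annotation table, and manual
curation is represented by a blacklist file. See `docs/methods.md` for the
model conventions, parameter defaults, and known limitations.
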