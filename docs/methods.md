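# Methods

## Scope and model

`proteorefine` treats genome annotation refinement as an evidence-driven
reconstruction problem.  The observables are: a set of annotated gene
models on a (possibly misassembled) genome, a table of MS/MS-identified
peptides, full-length protein records, and transcript records.  The
latent object is the true exon chain of each gene.  The pipeline never
predicts genes de novo; it only rebuilds models where peptide, protein or
transcript evidence demands it, and everything it cannot settle is
reported as `unresolved` rather than guessed.

Assumptions baked into the model:

- **Standard genetic code**, nuclear genes only.  Codons containing N
  translate to X (no ambiguity resolution), so assembly gaps cannot
  fabricate residues.
- **Canonical GT..AG introns only.**  The evidence in this problem class
  shows canonical sites; non-canonical candidates are reported
  unresolvable rather than scored probabilistically.
- **Exact peptide matching**, I/L-equivalent by default (the two residues
  are isobaric and indistinguishable by MS/MS); no mutations, no PTM mass
  shifts.  Peptides are assumed tryptic upstream; the in-silico digest
  uses the classical rule (cleave after K/R unless P follows) with
  defaults of ≤ 2 missed cleavages and length 7–35 aa, matching common
  search-engine settings.
- **Near-identity evidence.**  Fragment/full-length relationships in this
  setting are essentially exact, so similarity search is replaced by one
  deterministic internal aligner and exact substring search in six-frame
  space (see below).

## Pipeline stages (fixed order)

1. **Integrity checks** per model: start codon, internal stops, terminal
   stop, checked in that order against the genome.
2. **Inversion fixes.**  Each transcript is chained onto each contig by
   greedy maximal exact matching (both orientations; longest-prefix
   blocks ≥ 20 nt, co-linear).  If the majority of the transcript chains
   in one orientation while a contiguous remainder chains only in the
   opposite orientation, the spanned interval is flagged as an inverted
   assembly block; the block is reverse-complemented in the working
   genome and all models inside are re-coordinated and re-stranded.
   Inversions precede merges because a merge across an inverted block is
   only visible after re-stranding.  Orientation is decided by majority:
   the detection is symmetric when the inverted block carries at least
   half of the transcript, and such a case would be reported from the
   opposite frame of reference (both descriptions are internally
   consistent); the synthetic generator therefore keeps the un-inverted
   part of the gene in the majority.
3. **Peptide classification.**  Annotated proteome first (exact,
   I/L-folded, lifted to genomic blocks through the exon chain; one block
   = `exonic`, several = `junction`); six-frame genome search only for
   peptides with no annotated placement.  Genomic placements fully
   outside annotated CDS are `novel_region`; placements overlapping an
   annotated intron on the model's strand are `intron_retained`
   candidates; peptides placing at more than one distinct locus are
   downgraded to `ambiguous` and never used as evidence (models sharing
   exons, e.g. proteoforms of one gene, count as one locus).
4. **Fragment detection.**  Every model protein (translation truncated at
   the first stop) is aligned to every full-length evidence protein with
   the fixed-scoring glocal aligner (query global, target local; match
   +2, mismatch −1, gap open −5, gap extend −1, identity computed over
   aligned columns).  Placements need identity ≥ 0.95 and query coverage
   ≥ 0.9; a model that fails is retried on the opposite strand
   (wrong-strand annotations place `flipped`).  Placements ordered along
   the target with pairwise overlap ≤ 5 aa (signal-peptide/propeptide
   fuzz) form a fragment map.
5. **Reconstruction** per fragment map.  If a transcript whose
   translation equals the target chains completely onto one contig, its
   chain *is* the exon chain (transcript-first path; evidence tier
   `transcript`).  Otherwise the placements tile the target and each
   uncovered target segment is located exactly: its residues are searched
   as a substring of the six-frame ORF proteins (unique hit required).
   Internal segments must be flanked by a canonical acceptor and donor
   and supported by ≥ 1 unambiguous `novel_region` peptide; C-terminal
   segments must be followed by an in-frame stop (on the home contig this
   is a terminal-exon addition and needs a canonical acceptor; on another
   contig it is a cross-contig patch — an assembly continuation, where no
   splice site can be demanded).  Exons of input models that fall outside
   their placement's aligned span are removed as misclassified.  The
   assembled candidate must translate without internal stops, end with a
   stop, and align to the target at identity ≥ 0.95 with full target
   coverage; every seam between elements from different sources needs a
   junction peptide on the candidate unless the transcript vouches for
   the structure.  Failures leave the input models untouched, flagged
   `status=putative_fragment`, with the reason in the unresolved list.
6. **Intron retention.**  For each model with an in-frame
   `intron_retained` boundary peptide, the retained segment is the
   maximal stop-free intronic prefix whose length is divisible by 3,
   which contains the peptide's intronic overhang and is immediately
   followed by an alternative canonical GT donor.  The call emits the
   canonical/retained proteoform pair, a gene model for the retained form
   (boundary exon extended), and a ledger record; if every candidate
   prefix hits an in-frame stop the call is refused.

Idempotence: the refined GFF3 includes the retained proteoform as a
second mRNA of its gene, and inversion fixes are materialized in
`corrected_genome.fasta`, so a second run over the pipeline's own output
finds nothing to do.  Note that the truth *annotation* on the as-released
genome is not a fixed point: a physically inverted block and an
unannotated proteoform are still (correctly) reported even when every
gene model is right.

## Coordinates and formats

External GFF3 is 1-based inclusive, BED 0-based half-open; all internal
intervals are 0-based half-open, converted only at the I/O boundary.
Gene models are ordered exon chains in transcription order (index 0 = 5'
exon) with per-exon contig and strand, which represents cross-contig
patches and inversion-patched models without special cases; serialization
keeps multi-part models under one gene ID with `part=` and `order=`
attributes, and merged models carry `merged_from=`.

## The synthetic study

The generator emulates the study conditions this pipeline is built for:
a small protease-like gene family on a fragmented draft assembly, one
gene per anomaly class (A–H, see `synthetic_data` docstring), each on its
own contig set (~2–6 kb, intergenic padding ≥ 500 nt), total < 100 kb.
Genes are 90–160 codons with 4–9 codon-aligned exons and 60–150 nt
canonical introns; sequence is GC-uniform random with stop codons
excluded codon-wise, so frames are clean by construction rather than by
post-hoc editing.  Evidence comprises the complete fully-cleaved tryptic
digest (7–35 aa) of each truth protein plus the specific junction /
exon-internal / boundary peptides each correction requires; the
intron-retention scenario plants a 21-nt (7-residue) stop-free retained
segment bounded by an alternative donor, with an engineered tryptic cut
site so the boundary peptide is a clean digest product.  Builders redraw
deterministically (seeded) until structural guarantees hold: required
junction peptides exist as tryptic products, gap segments and genomic
peptides are unique in bundle-wide six-frame space, transcript chains
reproduce the truth exons exactly, and corrupted fragments visibly lack
start codons.

What the generator does **not** emulate — and hence what passing the
synthetic suite does not demonstrate: realistic codon usage and repeat
content (real genomes produce more ambiguous placements), MS noise
(false-positive PSMs, mass errors, PTMs; decoy peptides are available but
default off), incomplete digests, paralogy at high sequence identity
(which would trigger the ambiguity downgrade rather than wrong merges),
and non-canonical splice sites.

## The worked-example catalogue

`data/table1.json` encodes the curated A1 protease-family catalogue of
*R. prolixus*: 17 final entities carrying their input gene IDs, merge
groups, locations, transcript/protein accessions, masses (Daltons),
evidence class and correction class.  `summarize_table1()` derives every
reported count from the row data (15 genes, 7 corrections — the
intron-retention characterization is excluded from the correction count —
11 protein-tier, 2 transcript-only, 2 without evidence, 2 putative
fragments).  The 23 input gene IDs in the catalogue exceed the historical
count of 19 annotated family members; the summary reports what the data
contain and hard-codes nothing.  One transcript-only assignment
(R4G2R0) is an inference from the case narrative and is flagged in the
row's notes.

## Numerical choices

- Aligner scoring fixed (above); gap open is the score of a 1-residue
  gap.  The test suite holds the aligner to an independent pure-Python
  affine-gap DP oracle on pairs up to 300 aa.
- Fragment thresholds: identity 0.95, fragment coverage 0.9, overlap
  tolerance 5 aa, same-contig adjacency window 50 kb — all configurable
  (`Config`).
- Transcript chaining: minimum exact block 20 nt; splice-boundary
  ambiguity (identical bases on both sides of an intron) is resolved by
  sliding ≤ 6 nt toward canonical GT..AG.
- Six-frame scan keeps stretches ≥ 8 aa (the shortest credible tryptic
  evidence is 7 aa; gap-segment search uses the same index).
- Novel-exon boundary search window: 300 nt; equidistant canonical sites
  break toward the longer exon (keeps the evidence interior).
- Problem sizes in tests and the acceptance script (100 × 3 kb oracle
  contigs, 50 aligner pairs ≤ 300 aa, < 100 kb synthetic genome) were
  chosen so the whole verification runs in well under a minute while
  still exercising every code path; they are properties of the synthetic
  study design, and all results are deterministic given the seed.

## Known limitations

- Merges are only attempted where a full-length evidence protein exists;
  fragment pairs without one (the putative-fragment entities of the
  worked example) stay unresolved by design.
- Inversion breakpoints are evidenced only to the span of the wrong-
  orientation exon blocks; flanking non-coding sequence inside the true
  inverted block is not recovered.
- The exact-match transcript chainer assumes near-perfect transcript/
  genome identity; it is not a spliced aligner for diverged evidence.
- N-terminal gaps require transcript evidence; peptides alone cannot
  anchor a 5' extension because the start codon is not peptide-observable
  (N-terminal peptides are rarely tryptic-clean).
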