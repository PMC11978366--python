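# proteorefine

Proteogenomic refinement of gene annotations: map MS/MS-identified
peptides and transcript/protein evidence onto a genome, detect annotation
anomalies, consolidate fragmented gene models, infer unannotated exons,
and call intron-retention proteoforms.

## The problem

Draft genome annotations of non-model organisms are littered with broken
gene models: genes split into two or three fragments, exons missing or
misclassified as introns, models placed on the wrong strand over inverted
assembly blocks, and coding sequence lost across contig boundaries.  For
gene families studied at the protein level — here motivated by the A1
(pepsin-like) aspartic-protease family of the blood-feeding insect
*Rhodnius prolixus*, whose digestive proteases are candidate vector-control
targets — such errors inflate gene counts and hide real proteoforms.

Tandem-MS peptides are direct evidence of what a genome actually encodes.
`proteorefine` operationalizes the manual curation workflow that uses
them: each identified peptide is matched exactly (I/L-insensitively)
against the annotated proteome and lifted back through the exon chain to
genomic coding blocks; peptides that fail are searched in the six-frame
translation of the genome.  A peptide whose codons land in presumed
intergenic sequence evidences an unannotated exon; one that spans two
exons (a *junction peptide*) evidences their joint membership in one
transcript; one that crosses an exon/intron boundary in frame evidences
an intron-retention proteoform.  Full-length protein and transcript
records supply the scaffold: annotated isoforms that align as
near-disjoint fragments of one full-length protein (identity ≥ 0.95,
fragment coverage ≥ 0.9, overlap ≤ 5 aa) mark a fragmented gene, and the
uncovered stretches of the target protein are located exactly in
six-frame space, bounded by canonical GT/AG splice sites or an in-frame
stop.  Corrections are accepted only with bridging evidence — a junction
peptide across every new seam, or a transcript chain reproducing the
whole structure — and are recorded in a ledger; anything the evidence
cannot settle is reported `unresolved`, never guessed.

Eight anomaly classes are handled: gene fragmentation (2-way and 3-way,
within and across contigs), unannotated internal and terminal exons,
intronic sequence misannotated as an exon, wrong-strand models, inverted
assembly blocks, missing upstream exons, and intron retention via an
alternative canonical donor.

## Worked example

The package ships a synthetic-study generator that builds a small
multi-contig genome with one gene per anomaly class, corrupts the
annotation exactly as documented, and emits the evidence (tryptic
peptides, transcripts, full-length proteins) needed to recover the truth:

```
proteorefine generate --seed 42 -o data/
proteorefine refine --genome data/genome.fasta --models data/corrupted.gff3 \
    --peptides data/peptides.tsv --proteins data/proteins.fasta \
    --transcripts data/transcripts.fasta -o out/
```

The refine run prints one line per correction and ends with:

```
INFO correction intron_retention: geneH1 -> geneH1 (intron 2 retains 21 nt (7 aa)
     up to an alternative canonical donor); evidence: peptide:EEGWSGYHTVNSFNYK
INFO done: 13 -> 8 genes, 14 corrections, 0 unresolved
```

meaning: the 13 corrupted input models were consolidated into 8 genes; 14
ledger records were written (merges, novel exons, cross-contig patches,
an inversion fix, an upstream-exon addition, a misclassified-exon
removal, and one intron-retention proteoform call); nothing was left
unresolved.  `out/report.json` contains the bookkeeping
(`n_genes_before: 13, n_genes_after: 8, n_corrections: 7` — seven genes
were structurally corrected; the intron-retention call characterizes a
proteoform rather than repairing a model), the per-gene evidence tiers (6
protein-level, 2 transcript-only), the full ledger and the proteoform
table.  Re-running `refine` on `out/refined.gff3` yields an empty ledger:
the pipeline is idempotent.

`proteorefine report` prints the packaged worked-example bookkeeping for
the *R. prolixus* A1 protease family catalogue: 15 final genes from 23
input gene IDs, 7 corrected annotations, 11 genes supported at the
protein level, 2 by transcripts only, 2 without expression evidence, and
2 putative fragments.

## Layout

```
src/proteorefine/
  io_formats.py        FASTA/GFF3/TSV/BED readers and writers; coordinate rules
  seqcore.py           translation, spliced CDS, tryptic digestion, six-frame scan
  peptide_mapping.py   peptide placement and classification
  anomaly_detection.py integrity checks, protein aligner, fragment maps,
                       transcript chaining, inversion detection
  model_refinement.py  corrections, ledger, intron-retention calls
  evidence_report.py   evidence tiers and bookkeeping; worked-example fixture
  synthetic_data.py    scenario generator (ground truth for every anomaly class)
  cli.py               generate / refine / report subcommands
docs/methods.md        model, parameters, assumptions, limitations
```
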