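"""Placement of MS/MS peptides on the annotated proteome and the genome.

Each peptide is first searched in the spliced proteins of the annotated
gene models (exact match, optionally I/L-insensitive) and lifted back
through the exon chain to genomic coding blocks.  Peptides that fail the
annotated search are looked up in the six-frame translation of the genome;
placements landing outside annotated CDS are evidence of unannotated
exons, placements inside annotated introns are candidate intron-retention
proteoforms, and peptides placing at several loci are downgraded to
ambiguous and never used as refinement evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .config import Config
from .io_formats import Exon, GeneModel, PeptideRecord
from .seqcore import OrfHit, six_frame_scan, spliced_cds

__all__ = [
    "PeptideGenomicHit",
    "AnnotationIndex",
    "map_to_annotated",
    "map_to_genome",
    "classify_all",
    "hits_to_bed",
]

CATEGORIES = frozenset(
    {"exonic", "junction", "novel_region", "intron_retained", "ambiguous", "unmapped"}
)


def fold_il(seq: str) -> str:
    """Collapse I/L (isobaric residues MS cannot distinguish)."""
    return seq.replace("L", "I")


@dataclass
class PeptideGenomicHit:
    """A peptide placed on the genome as one or more coding blocks."""

    peptide: PeptideRecord
    contig: str | None
    strand: str | None
    blocks: list[Exon]
    category: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.blocks:
            total = sum(len(b) for b in self.blocks)
            if total != 3 * len(self.peptide.sequence):
                raise ValueError(
                    f"block lengths sum to {total}, expected "
                    f"{3 * len(self.peptide.sequence)}"
                )
        if self.category == "junction" and len(self.blocks) < 2:
            raise ValueError("junction hits need >= 2 blocks")

    def locus_key(self) -> tuple:
        return tuple((b.contig, b.start, b.end, b.strand) for b in self.blocks)


def _lift_to_blocks(model: GeneModel, nt_start: int, nt_end: int) -> list[Exon]:
    """Project a CDS nucleotide interval through the exon chain to genomic
    blocks, ordered 5'->3' in transcription order."""
    blocks = []
    offset = 0
    for exon in model.exons:
        e_len = len(exon)
        lo = max(nt_start, offset)
        hi = min(nt_end, offset + e_len)
        if lo < hi:
            a, b = lo - offset, hi - offset  # local within exon
            if exon.strand == "+":
                blocks.append(
                    Exon(exon.contig, exon.start + a, exon.start + b, "+")
                )
            else:
                blocks.append(
                    Exon(exon.contig, exon.end - b, exon.end - a, "-")
                )
        offset += e_len
    return blocks


def map_to_annotated(
    peptide: PeptideRecord,
    models: list[GeneModel],
    genome: dict[str, str],
    il_equivalent: bool = True,
    protein_cache: dict[str, str] | None = None,
) -> list[PeptideGenomicHit]:
    """All occurrences of a peptide in the spliced proteins of the models,
    lifted back to genomic blocks.

    Occurrences crossing an exon boundary are classified ``junction``,
    single-block occurrences ``exonic``.
    """
    fold = fold_il if il_equivalent else (lambda s: s)
    needle = fold(peptide.sequence)
    hits = []
    for model in models:
        if protein_cache is not None and model.gene_id in protein_cache:
            protein = protein_cache[model.gene_id]
        else:
            _, protein = spliced_cds(model, genome)
            protein = protein.rstrip("*")
            if protein_cache is not None:
                protein_cache[model.gene_id] = protein
        hay = fold(protein)
        start = hay.find(needle)
        while start >= 0:
            nt_lo, nt_hi = 3 * start, 3 * (start + len(needle))
            blocks = _lift_to_blocks(model, nt_lo, nt_hi)
            hits.append(
                PeptideGenomicHit(
                    peptide=peptide,
                    contig=blocks[0].contig,
                    strand=blocks[0].strand,
                    blocks=blocks,
                    category="junction" if len(blocks) > 1 else "exonic",
                    gene_id=model.gene_id,
                )
            )
            start = hay.find(needle, start + 1)
    return hits


@dataclass
class AnnotationIndex:
    """CDS mask and intron catalogue of an annotation, for hit classification."""

    mask: dict[str, IntervalTree] = field(default_factory=dict)
    introns: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def build(cls, models: list[GeneModel]) -> "AnnotationIndex":
        idx = cls()
        for m in models:
            for e in m.exons:
                idx.mask.setdefault(e.contig, IntervalTree()).addi(
                    e.start, e.end, m.gene_id
                )
            for a, b in zip(m.exons, m.exons[1:]):
                if a.contig != b.contig or a.strand != b.strand:
                    continue
                lo, hi = min(a.end, b.end), max(a.start, b.start)
                if lo < hi:
                    idx.introns.setdefault(a.contig, IntervalTree()).addi(
                        lo, hi, (m.gene_id, a.strand)
                    )
        return idx

    def in_mask(self, contig: str, start: int, end: int) -> bool:
        tree = self.mask.get(contig)
        return bool(tree and tree.overlap(start, end))

    def intron_gene(self, contig: str, start: int, end: int, strand: str) -> str | None:
        tree = self.introns.get(contig)
        if not tree:
            return None
        for iv in sorted(tree.overlap(start, end)):
            gene_id, istrand = iv.data
            if istrand == strand:
                return gene_id
        return None


def _orf_occurrences(
    needle: str, orfs: list[OrfHit], il_equivalent: bool
) -> list[tuple[OrfHit, int]]:
    fold = fold_il if il_equivalent else (lambda s: s)
    needle = fold(needle)
    occs = []
    for orf in orfs:
        hay = fold(orf.protein)
        p = hay.find(needle)
        while p >= 0:
            occs.append((orf, p))
            p = hay.find(needle, p + 1)
    return occs


def map_to_genome(
    peptide: PeptideRecord,
    genome: dict[str, str],
    annotation: AnnotationIndex,
    il_equivalent: bool = True,
    orf_cache: dict[str, list[OrfHit]] | None = None,
    min_orf_len: int = 8,
) -> list[PeptideGenomicHit]:
    """Search the six-frame translated genome for a peptide.

    Placements fully outside annotated CDS are ``novel_region``; placements
    overlapping an annotated intron on the model's strand are candidate
    ``intron_retained``; anything else, and every placement of a
    multi-locus peptide, is ``ambiguous``.
    """
    if orf_cache is None:
        orf_cache = {}
    occs = []
    for contig_id, seq in genome.items():
        if contig_id not in orf_cache:
            orf_cache[contig_id] = six_frame_scan(seq, min_orf_len, contig_id)
        occs.extend(_orf_occurrences(peptide.sequence, orf_cache[contig_id], il_equivalent))

    hits = []
    n = len(peptide.sequence)
    for orf, p in occs:
        if orf.strand == "+":
            gs = orf.start + 3 * p
            ge = gs + 3 * n
        else:
            ge = orf.end - 3 * p
            gs = ge - 3 * n
        block = Exon(orf.contig, gs, ge, orf.strand)
        intron_gene = annotation.intron_gene(orf.contig, gs, ge, orf.strand)
        if intron_gene is not None:
            category, gene = "intron_retained", intron_gene
        elif not annotation.in_mask(orf.contig, gs, ge):
            category, gene = "novel_region", None
        else:
            category, gene = "ambiguous", None
        hits.append(
            PeptideGenomicHit(
                peptide=peptide,
                contig=orf.contig,
                strand=orf.strand,
                blocks=[block],
                category=category,
                gene_id=gene,
            )
        )
    distinct = {h.locus_key() for h in hits}
    if len(distinct) > 1:
        for h in hits:
            h.category = "ambiguous"
    return hits


def classify_all(
    peptides: list[PeptideRecord],
    models: list[GeneModel],
    genome: dict[str, str],
    config: Config | None = None,
    orf_cache: dict[str, list[OrfHit]] | None = None,
) -> list[PeptideGenomicHit]:
    """Classify every peptide: annotated mapping first, then genome search
    for peptides with no annotated hit (or always, in exhaustive mode).

    Peptides with zero hits yield a single ``unmapped`` record.  A peptide
    whose placements (annotated or genomic) cover more than one distinct
    locus has all its hits downgraded to ``ambiguous``.
    """
    config = config or Config()
    annotation = AnnotationIndex.build(models)
    protein_cache: dict[str, str] = {}
    out = []
    for pep in peptides:
        hits = map_to_annotated(
            pep, models, genome, config.il_equivalent, protein_cache
        )
        if not hits or config.exhaustive:
            hits.extend(
                map_to_genome(
                    pep,
                    genome,
                    annotation,
                    config.il_equivalent,
                    orf_cache,
                    config.min_orf_len,
                )
            )
        distinct = {h.locus_key() for h in hits}
        if len(distinct) > 1:
            # several models sharing exons (e.g. proteoforms) are one locus;
            # genuinely distinct loci make the peptide ambiguous
            merged = _merge_locus_keys(distinct)
            if len(merged) > 1:
                for h in hits:
                    h.category = "ambiguous"
        if not hits:
            hits = [
                PeptideGenomicHit(
                    peptide=pep, contig=None, strand=None, blocks=[],
                    category="unmapped",
                )
            ]
        out.extend(hits)
    return out


def _merge_locus_keys(keys: set[tuple]) -> list[set]:
    """Group locus keys that overlap genomically (shared exons)."""
    groups: list[tuple[set, list]] = []  # (set of (contig,strand) spans, keys)
    for key in keys:
        spans = [(c, s, e, st) for c, s, e, st in key]
        placed = None
        for group_spans, group_keys in groups:
            if any(
                c == gc and st == gst and s < ge and gs < e
                for (c, s, e, st) in spans
                for (gc, gs, ge, gst) in group_spans
            ):
                placed = (group_spans, group_keys)
                break
        if placed:
            placed[0].update(spans)
            placed[1].append(key)
        else:
            groups.append((set(spans), [key]))
    return [g for _, g in groups]


def hits_to_bed(hits: list[PeptideGenomicHit]):
    """Extended BED6 rows (category in column 7) for mapped hits."""
    for h in hits:
        for b in h.blocks:
            yield (
                b.contig,
                b.start,
                b.end,
                h.peptide.sequence,
                h.peptide.psm_count,
                b.strand,
                h.category,
            )
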