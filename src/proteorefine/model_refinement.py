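"""Application of annotation corrections.

Given gene models, a genome, peptide hits, evidence proteins and
transcripts, this module rebuilds the gene models the evidence demands:
fragmented models are merged, unannotated exons are inferred from
peptide-supported intervals and evidence-protein gap filling, assembly
splits are patched across contigs, inverted blocks are re-oriented,
missing 5' exons are recovered from transcript chains, and
intron-retention proteoforms are called.  Every transformation is recorded
in a ledger of :class:`CorrectionRecord` entries; cases the evidence
cannot settle land in an ``unresolved`` list instead of being guessed.

Stage order is fixed: integrity checks, inversion fixes, peptide
classification, fragment detection, reconstruction (novel exons, merges,
patches, upstream additions), intron retention.  Inversions are corrected
before merges because a merge across an inverted block is only visible
after re-stranding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .anomaly_detection import (
    Anomaly,
    FragmentMap,
    align_proteins,
    check_model_integrity,
    detect_fragment_relation,
    detect_inversion,
    model_protein,
    spliced_align_transcript,
)
from .config import Config
from .io_formats import Exon, GeneModel, PeptideRecord, SeqRecord
from .peptide_mapping import (
    PeptideGenomicHit,
    classify_all,
    fold_il,
    map_to_annotated,
)
from .seqcore import STOP_CODONS, OrfHit, revcomp, spliced_cds, translate

__all__ = [
    "CorrectionRecord",
    "ProteoformPair",
    "UnresolvedCase",
    "RefinementResult",
    "infer_novel_exon",
    "correct_inversion",
    "call_intron_retention",
    "refine_all",
]

CORRECTION_CLASSES = frozenset(
    {
        "merge",
        "novel_exon",
        "terminal_exon_addition",
        "misclassified_exon_removal",
        "cross_contig_patch",
        "inversion_fix",
        "upstream_exon_addition",
        "intron_retention",
    }
)


@dataclass
class CorrectionRecord:
    """One ledger entry transforming input gene IDs into an output model."""

    cls: str
    input_gene_ids: tuple[str, ...]
    output_gene_id: str | None
    output_model: GeneModel | None
    evidence: tuple[str, ...]
    detail: str = ""
    evidence_tier: str = "protein"  # protein | transcript

    def __post_init__(self) -> None:
        if self.cls not in CORRECTION_CLASSES:
            raise ValueError(f"unknown correction class {self.cls!r}")
        if not self.evidence:
            raise ValueError("a correction must cite at least one evidence item")


@dataclass(frozen=True)
class ProteoformPair:
    """Canonical and intron-retained proteoforms of one gene."""

    gene_id: str
    canonical: str
    retained: str
    retained_intron_index: int  # 1-based
    extra_residues: int

    def __post_init__(self) -> None:
        if len(self.retained) - len(self.canonical) != self.extra_residues:
            raise ValueError("retained form must add exactly extra_residues")


@dataclass(frozen=True)
class UnresolvedCase:
    gene_ids: tuple[str, ...]
    reason: str


@dataclass
class RefinementResult:
    genome: dict[str, str]
    models: list[GeneModel]
    records: list[CorrectionRecord]
    unresolved: list[UnresolvedCase]
    hits: list[PeptideGenomicHit]
    proteoforms: list[ProteoformPair]
    anomalies: list[Anomaly]

    def record_classes(self) -> list[str]:
        return [r.cls for r in self.records]


# ---------------------------------------------------------------------------
# Strand-aware flank helpers (0-based half-open genomic interval [s, e))

def _has_acceptor_before(contig: str, s: int, e: int, strand: str) -> bool:
    """Canonical acceptor AG immediately 5' of an exon interval."""
    if strand == "+":
        return s >= 2 and contig[s - 2 : s] == "AG"
    return e + 2 <= len(contig) and contig[e : e + 2] == "CT"  # revcomp(AG)


def _has_donor_after(contig: str, s: int, e: int, strand: str) -> bool:
    """Canonical donor GT immediately 3' of an exon interval."""
    if strand == "+":
        return e + 2 <= len(contig) and contig[e : e + 2] == "GT"
    return s >= 2 and contig[s - 2 : s] == "AC"  # revcomp(GT)


def _stop_follows(contig: str, s: int, e: int, strand: str) -> bool:
    """In-frame stop codon immediately 3' of an interval."""
    if strand == "+":
        return e + 3 <= len(contig) and contig[e : e + 3] in STOP_CODONS
    return s >= 3 and revcomp(contig[s - 3 : s]) in STOP_CODONS


# ---------------------------------------------------------------------------
# Novel-exon inference from peptide-supported intervals


def infer_novel_exon(
    hits: list[PeptideGenomicHit],
    genome: dict[str, str],
    window: int = 300,
    terminal: bool = False,
) -> Exon | None:
    """Extend a peptide-supported interval outward to canonical boundaries.

    All hits must share contig, strand and reading frame (conflicting
    frames are an error).  For an internal exon the interval grows to the
    nearest in-frame canonical acceptor (5') and donor (3') within
    ``window``; for a terminal exon the 3' boundary is the nearest in-frame
    stop codon and the returned exon includes it.  Returns None when no
    canonical boundary is reachable (the candidate is unresolvable).
    """
    if not hits:
        raise ValueError("no supporting hits")
    blocks = [b for h in hits for b in h.blocks]
    contigs = {b.contig for b in blocks}
    strands = {b.strand for b in blocks}
    if len(contigs) > 1 or len(strands) > 1:
        raise ValueError("hits disagree on contig/strand")
    contig_id, strand = contigs.pop(), strands.pop()
    seq = genome[contig_id]
    frames = {
        (b.start % 3) if b.strand == "+" else ((len(seq) - b.end) % 3)
        for b in blocks
    }
    if len(frames) > 1:
        raise ValueError(
            "conflicting reading frames among supporting hits: "
            + ", ".join(h.peptide.sequence for h in hits)
        )
    lo = min(b.start for b in blocks)
    hi = max(b.end for b in blocks)

    def stop_free(s: int, e: int) -> bool:
        sub = seq[s:e] if strand == "+" else revcomp(seq[s:e])
        return "*" not in translate(sub)

    # 5' boundary: nearest in-frame acceptor moving outward
    if strand == "+":
        starts = range(lo, max(lo - window, 0) - 1, -3)
        start5 = next(
            (a for a in starts if _has_acceptor_before(seq, a, hi, "+") and stop_free(a, hi)),
            None,
        )
    else:
        ends = range(hi, min(hi + window, len(seq)) + 1, 3)
        start5 = next(
            (b for b in ends if _has_acceptor_before(seq, lo, b, "-") and stop_free(lo, b)),
            None,
        )
    if start5 is None:
        return None

    # 3' boundary: nearest in-frame donor (internal) or stop codon (terminal)
    if strand == "+":
        s_new = start5
        if terminal:
            cands = range(hi, min(hi + window, len(seq) - 2) + 1, 3)
            e_new = next(
                (b + 3 for b in cands if _stop_follows(seq, s_new, b, "+") and stop_free(s_new, b)),
                None,
            )
        else:
            cands = range(hi, min(hi + window, len(seq)) + 1, 3)
            e_new = next(
                (b for b in cands if _has_donor_after(seq, s_new, b, "+") and stop_free(s_new, b)),
                None,
            )
        if e_new is None:
            return None
        return Exon(contig_id, s_new, e_new, "+")
    else:
        e_new = start5
        if terminal:
            cands = range(lo, max(lo - window, 3) - 1, -3)
            s_new = next(
                (a - 3 for a in cands if _stop_follows(seq, a, e_new, "-") and stop_free(a, e_new)),
                None,
            )
        else:
            cands = range(lo, max(lo - window, 0) - 1, -3)
            s_new = next(
                (a for a in cands if _has_donor_after(seq, a, e_new, "-") and stop_free(a, e_new)),
                None,
            )
        if s_new is None:
            return None
        return Exon(contig_id, s_new, e_new, "-")


# ---------------------------------------------------------------------------
# Inversion correction


def correct_inversion(
    genome: dict[str, str],
    contig_id: str,
    interval: tuple[int, int],
    models: list[GeneModel],
    evidence: tuple[str, ...],
) -> tuple[dict[str, str], list[GeneModel], CorrectionRecord]:
    """Reverse-complement an inverted assembly block and remap models.

    Exons fully inside the interval are re-coordinated and re-stranded;
    exon order within each model is preserved (it encodes transcription
    order, which the inversion does not change).  Exons straddling a
    breakpoint cannot be remapped and raise.
    """
    lo, hi = interval
    seq = genome[contig_id]
    new_genome = dict(genome)
    new_genome[contig_id] = seq[:lo] + revcomp(seq[lo:hi]) + seq[hi:]

    def remap_exon(e: Exon) -> Exon:
        if e.contig != contig_id or e.end <= lo or e.start >= hi:
            return e
        if e.start < lo or e.end > hi:
            raise ValueError(
                f"exon [{e.start},{e.end}) straddles inversion breakpoint "
                f"[{lo},{hi})"
            )
        return Exon(
            contig_id,
            lo + hi - e.end,
            lo + hi - e.start,
            "+" if e.strand == "-" else "-",
        )

    new_models = []
    affected = []
    for m in models:
        exons = [remap_exon(e) for e in m.exons]
        if exons != m.exons:
            affected.append(m.gene_id)
            strand = max(set(e.strand for e in exons),
                         key=lambda s: sum(len(e) for e in exons if e.strand == s))
            new_models.append(replace(m, exons=exons, strand=strand))
        else:
            new_models.append(m)
    record = CorrectionRecord(
        cls="inversion_fix",
        input_gene_ids=tuple(affected) or ("unannotated",),
        output_gene_id=None,
        output_model=None,
        evidence=evidence,
        detail=f"{contig_id}:[{lo},{hi}) reverse-complemented",
        evidence_tier="transcript",
    )
    return new_genome, new_models, record


# ---------------------------------------------------------------------------
# Intron retention


def call_intron_retention(
    model: GeneModel,
    hits: list[PeptideGenomicHit],
    genome: dict[str, str],
) -> tuple[ProteoformPair, GeneModel, CorrectionRecord] | None:
    """Call an intron-retention proteoform from exon/intron boundary peptides.

    The retained segment is the maximal in-frame, stop-free intronic prefix
    bounded by an alternative canonical donor; it must contain the intronic
    part of the evidence peptide.  Returns the proteoform pair, a gene
    model for the retained form (boundary exon extended), and the ledger
    record -- or None when no valid retained segment exists (e.g. every
    candidate prefix hits an in-frame stop) or no peptide crosses the
    junction.
    """
    mrna, protein = spliced_cds(model, genome)
    canonical = protein.rstrip("*")
    strand = model.strand
    contig = genome[model.contig]

    # introns in transcription order, with the CDS offset of their 5' edge
    introns = []
    offset = 0
    for a, b in zip(model.exons, model.exons[1:]):
        offset += len(a)
        if a.contig != b.contig:
            introns.append(None)
            continue
        if strand == "+":
            introns.append((a.end, b.start, offset))
        else:
            introns.append((b.end, a.start, offset))

    for k, intron in enumerate(introns):
        if intron is None:
            continue
        i_lo, i_hi, cds_offset = intron
        boundary = i_lo if strand == "+" else i_hi  # genomic junction point
        crossing = []
        for h in hits:
            for blk in h.blocks:
                if blk.contig != model.contig or blk.strand != strand:
                    continue
                if blk.start < boundary < blk.end:
                    over = (blk.end - boundary) if strand == "+" else (boundary - blk.start)
                    crossing.append((h, over))
        if not crossing:
            continue
        need = max(over for _, over in crossing)
        intron_len = i_hi - i_lo

        def prefix_seq(L: int) -> str:
            if strand == "+":
                return contig[i_lo : i_lo + L]
            return revcomp(contig[i_hi - L : i_hi])

        def alt_donor_after(L: int) -> bool:
            if L + 2 > intron_len:
                return False
            if strand == "+":
                return contig[i_lo + L : i_lo + L + 2] == "GT"
            return revcomp(contig[i_hi - L - 2 : i_hi - L]) == "GT"

        best = None
        for L in range((intron_len - 4) // 3 * 3, 0, -3):
            if L < need:
                break
            seg = prefix_seq(L)
            if not alt_donor_after(L):
                continue
            retained_mrna = mrna[:cds_offset] + seg + mrna[cds_offset:]
            retained_prot = translate(retained_mrna)
            if "*" in retained_prot.rstrip("*") or not retained_prot.endswith("*"):
                continue
            best = (L, retained_prot.rstrip("*"))
            break
        if best is None:
            continue
        L, retained = best
        # the evidence peptide must actually occur in the retained form
        supported = [
            h for h, _ in crossing
            if fold_il(h.peptide.sequence) in fold_il(retained)
        ]
        if not supported:
            continue
        exons = list(model.exons)
        e = exons[k]
        exons[k] = (
            replace(e, end=e.end + L) if strand == "+" else replace(e, start=e.start - L)
        )
        retained_model = GeneModel(
            gene_id=f"{model.gene_id}.ir1",
            contig=model.contig,
            strand=strand,
            exons=exons,
            has_start=model.has_start,
            has_stop=True,
            attributes={
                "proteoform_of": model.gene_id,
                "retained_intron": str(k + 1),
                "extra_residues": str(L // 3),
            },
        )
        pair = ProteoformPair(
            gene_id=model.gene_id,
            canonical=canonical,
            retained=retained,
            retained_intron_index=k + 1,
            extra_residues=L // 3,
        )
        record = CorrectionRecord(
            cls="intron_retention",
            input_gene_ids=(model.gene_id,),
            output_gene_id=model.gene_id,
            output_model=retained_model,
            evidence=tuple(f"peptide:{h.peptide.sequence}" for h in supported),
            detail=(
                f"intron {k + 1} retains {L} nt ({L // 3} aa) up to an "
                f"alternative canonical donor"
            ),
        )
        return pair, retained_model, record
    return None


# ---------------------------------------------------------------------------
# Fragment-map reconstruction


def _exon_nt_ranges(model: GeneModel) -> list[tuple[Exon, int, int]]:
    out = []
    offset = 0
    for e in model.exons:
        out.append((e, offset, offset + len(e)))
        offset += len(e)
    return out


@dataclass
class _PendingRecord:
    cls: str
    input_gene_ids: tuple[str, ...]
    evidence: tuple[str, ...]
    detail: str = ""


def _find_gap_segment(
    gap_seg: str,
    orf_cache: dict[str, list[OrfHit]],
    genome: dict[str, str],
    want_stop_after: bool,
) -> list[tuple[str, int, int, str]]:
    """Genomic intervals whose translation equals ``gap_seg`` exactly,
    optionally followed by an in-frame stop codon."""
    found = []
    n = len(gap_seg)
    for contig_id, orfs in orf_cache.items():
        seq = genome[contig_id]
        for orf in orfs:
            p = orf.protein.find(gap_seg)
            while p >= 0:
                if orf.strand == "+":
                    gs = orf.start + 3 * p
                    ge = gs + 3 * n
                else:
                    ge = orf.end - 3 * p
                    gs = ge - 3 * n
                if not want_stop_after or _stop_follows(seq, gs, ge, orf.strand):
                    found.append((contig_id, gs, ge, orf.strand))
                p = orf.protein.find(gap_seg, p + 1)
    return found


def _peptide_support(
    hits: list[PeptideGenomicHit],
    contig: str,
    lo: int,
    hi: int,
    strand: str,
) -> list[PeptideGenomicHit]:
    """Unambiguous novel-region hits whose blocks lie within an interval."""
    out = []
    for h in hits:
        if h.category != "novel_region":
            continue
        if all(
            b.contig == contig and b.strand == strand and lo <= b.start and b.end <= hi
            for b in h.blocks
        ):
            out.append(h)
    return out


class _ReconstructionFailure(Exception):
    pass


def _reconstruct_one(
    fmap: FragmentMap,
    models_by_id: dict[str, GeneModel],
    target: str,
    genome: dict[str, str],
    orf_cache: dict[str, list[OrfHit]],
    hits: list[PeptideGenomicHit],
    transcripts: list[SeqRecord],
    config: Config,
) -> tuple[GeneModel | None, list[CorrectionRecord]]:
    """Rebuild the gene a fragment map describes.  Returns (model, records);
    model None means the map required no change.  Raises
    :class:`_ReconstructionFailure` when the evidence cannot settle it."""
    placements = sorted(fmap.placements, key=lambda p: p.target_span)
    input_ids = [p.gene_id for p in placements]
    linked_tx = [
        t for t in transcripts if translate(t.sequence).rstrip("*") == target
    ]

    # no-op: a single clean placement covering the whole target
    if len(placements) == 1 and not placements[0].flipped:
        m = models_by_id[placements[0].gene_id]
        span = placements[0].target_span
        if span[0] == 0 and span[1] >= len(target) and not check_model_integrity(m, genome):
            return None, []

    pending: list[_PendingRecord] = []
    elements: list[tuple[int, list[Exon]]] = []  # (target residue offset, exons)
    removed_by_model: dict[str, list[Exon]] = {}

    # --- transcript-first reconstruction -----------------------------------
    chain_model = None
    for tx in linked_tx:
        by_contig = {}
        for contig_id, seq in genome.items():
            chain = spliced_align_transcript(
                tx.sequence, seq, contig_id, config.min_block
            )
            by_contig[contig_id] = chain
        best = max(by_contig.values(), key=lambda c: c.coverage)
        if best.coverage >= 0.999 and best.spliced_sequence(genome) == tx.sequence:
            chain_model = (tx, best)
            break

    if chain_model is not None:
        tx, chain = chain_model
        exons = list(chain.exons)
        new_id = "-".join(input_ids) if len(input_ids) > 1 else input_ids[0]
        evidence = (f"transcript:{tx.id}", f"protein:{fmap.full_length_id}")
        if len(input_ids) > 1:
            pending.append(
                _PendingRecord("merge", tuple(input_ids), evidence,
                               f"{len(input_ids)} fragments joined by transcript chain")
            )
        else:
            m = models_by_id[input_ids[0]]
            old = {(e.contig, e.start, e.end) for e in m.exons}
            added = [e for e in exons if (e.contig, e.start, e.end) not in old]
            m_span = m.span()
            upstream = [
                e for e in added
                if (chain.strand == "+" and e.end <= m_span[0])
                or (chain.strand == "-" and e.start >= m_span[1])
            ]
            if upstream:
                pending.append(
                    _PendingRecord(
                        "upstream_exon_addition", tuple(input_ids), evidence,
                        f"{len(upstream)} upstream exon(s) recovered from transcript",
                    )
                )
            elif added:
                pending.append(
                    _PendingRecord("novel_exon", tuple(input_ids), evidence,
                                   f"{len(added)} exon(s) recovered from transcript")
                )
            if not added:
                return None, []
        out_model = GeneModel(
            gene_id=new_id,
            contig=exons[0].contig,
            strand=chain.strand,
            exons=exons,
            attributes={"evidence_tier": "transcript"},
        )
        return _finalize(
            out_model, input_ids, target, fmap, genome, hits, pending,
            removed_by_model, config, tier="transcript", new_seams=set(),
        )

    # --- placement/gap reconstruction --------------------------------------
    covered: list[tuple[int, int]] = []
    for p in placements:
        m = models_by_id[p.gene_id]
        if p.flipped:
            m = m.flipped()
        prot = model_protein(m, genome)
        res = align_proteins(prot, target)
        qa, qb = res.query_span
        kept, removed = [], []
        for e, nt_lo, nt_hi in _exon_nt_ranges(m):
            if nt_lo < 3 * qb and 3 * qa < nt_hi:
                kept.append(e)
            else:
                removed.append(e)
        if removed:
            removed_by_model[p.gene_id] = removed
        elements.append((p.target_span[0], kept))
        covered.append(p.target_span)
        if p.flipped:
            pending.append(
                _PendingRecord(
                    "merge", (p.gene_id,), (f"protein:{fmap.full_length_id}",),
                    f"{p.gene_id} re-stranded to match the evidence protein",
                )
            )

    # uncovered target segments
    gaps = []
    pos = 0
    for lo, hi in sorted(covered):
        if lo - pos > 0:
            gaps.append((pos, lo))
        pos = max(pos, hi)
    if len(target) - pos > 0:
        gaps.append((pos, len(target)))

    gene_strand = None
    all_exons_so_far = [e for _, ex in elements for e in ex]
    if all_exons_so_far:
        gene_strand = max(
            set(e.strand for e in all_exons_so_far),
            key=lambda s: sum(len(e) for e in all_exons_so_far if e.strand == s),
        )

    for glo, ghi in gaps:
        gseg = target[glo:ghi]
        terminal = ghi == len(target)
        n_terminal = glo == 0
        if n_terminal:
            raise _ReconstructionFailure(
                f"missing N-terminal residues 0..{ghi} of {fmap.full_length_id} "
                "and no transcript chain covers them"
            )
        cands = _find_gap_segment(gseg, orf_cache, genome, want_stop_after=terminal)
        cands = [c for c in cands if c[3] == gene_strand] or cands
        if not cands:
            raise _ReconstructionFailure(
                f"no genomic placement for residues {glo}..{ghi} of "
                f"{fmap.full_length_id}"
            )
        if len(cands) > 1:
            raise _ReconstructionFailure(
                f"ambiguous genomic placement for residues {glo}..{ghi} of "
                f"{fmap.full_length_id}"
            )
        contig_id, gs, ge, strand = cands[0]
        seq = genome[contig_id]
        home_contig = all_exons_so_far[0].contig if all_exons_so_far else contig_id
        if terminal:
            # include the stop codon in the terminal exon
            if strand == "+":
                exon = Exon(contig_id, gs, ge + 3, strand)
            else:
                exon = Exon(contig_id, gs - 3, ge, strand)
            if contig_id != home_contig:
                pending.append(
                    _PendingRecord(
                        "cross_contig_patch", tuple(input_ids),
                        (f"protein:{fmap.full_length_id}",),
                        f"C-terminal segment recovered on {contig_id}:"
                        f"[{exon.start},{exon.end})",
                    )
                )
            else:
                if not _has_acceptor_before(seq, gs, ge, strand):
                    raise _ReconstructionFailure(
                        f"terminal exon candidate {contig_id}:[{gs},{ge}) "
                        "lacks a canonical acceptor"
                    )
                support = _peptide_support(hits, contig_id, exon.start, exon.end, strand)
                pending.append(
                    _PendingRecord(
                        "terminal_exon_addition", tuple(input_ids),
                        tuple(f"peptide:{h.peptide.sequence}" for h in support)
                        or (f"protein:{fmap.full_length_id}",),
                        f"terminal exon {contig_id}:[{exon.start},{exon.end}) "
                        "ending at an in-frame stop",
                    )
                )
        else:
            exon = Exon(contig_id, gs, ge, strand)
            if not (
                _has_acceptor_before(seq, gs, ge, strand)
                and _has_donor_after(seq, gs, ge, strand)
            ):
                raise _ReconstructionFailure(
                    f"novel exon candidate {contig_id}:[{gs},{ge}) lacks "
                    "canonical splice sites"
                )
            support = _peptide_support(hits, contig_id, gs, ge, strand)
            if len(support) < config.min_peptides:
                raise _ReconstructionFailure(
                    f"novel exon {contig_id}:[{gs},{ge}) for residues "
                    f"{glo}..{ghi} of {fmap.full_length_id} has "
                    f"{len(support)} supporting peptide(s), "
                    f"need {config.min_peptides}"
                )
            pending.append(
                _PendingRecord(
                    "novel_exon", tuple(input_ids),
                    tuple(f"peptide:{h.peptide.sequence}" for h in support),
                    f"novel exon {contig_id}:[{gs},{ge}) encodes residues "
                    f"{glo}..{ghi} of {fmap.full_length_id}",
                )
            )
        elements.append((glo, [exon]))

    if len(input_ids) > 1:
        pending.append(
            _PendingRecord(
                "merge", tuple(input_ids), (f"protein:{fmap.full_length_id}",),
                f"{len(input_ids)} fragments of {fmap.full_length_id} merged",
            )
        )
        # fold standalone re-strand notes into the merge
        pending = [
            p for p in pending
            if not (p.cls == "merge" and len(p.input_gene_ids) == 1)
        ]

    elements.sort(key=lambda el: el[0])
    exons = [e for _, ex in elements for e in ex]
    if not pending:
        return None, []
    # CDS offsets (nt) of the junctions between elements: these are the new
    # seams the inputs did not contain, each needing a bridging peptide
    new_seams = set()
    acc = 0
    for i, (_, ex) in enumerate(elements):
        acc += sum(len(e) for e in ex)
        if i < len(elements) - 1:
            new_seams.add(acc)
    new_id = "-".join(input_ids) if len(input_ids) > 1 else input_ids[0]
    out_model = GeneModel(
        gene_id=new_id,
        contig=exons[0].contig,
        strand=max(set(e.strand for e in exons),
                   key=lambda s: sum(len(e) for e in exons if e.strand == s)),
        exons=exons,
        attributes={},
    )
    return _finalize(
        out_model, input_ids, target, fmap, genome, hits, pending,
        removed_by_model, config, tier="protein", new_seams=new_seams,
    )


def _finalize(
    model: GeneModel,
    input_ids: list[str],
    target: str,
    fmap: FragmentMap,
    genome: dict[str, str],
    hits: list[PeptideGenomicHit],
    pending: list[_PendingRecord],
    removed_by_model: dict[str, list[Exon]],
    config: Config,
    tier: str,
    new_seams: set[int],
) -> tuple[GeneModel, list[CorrectionRecord]]:
    """Validate a candidate model against evidence and emit its records."""
    mrna, protein = spliced_cds(model, genome)
    body = protein.rstrip("*")
    if "*" in body:
        raise _ReconstructionFailure(
            f"reconstruction of {fmap.full_length_id} yields an internal stop"
        )
    if not protein.endswith("*"):
        raise _ReconstructionFailure(
            f"reconstruction of {fmap.full_length_id} lacks a stop codon"
        )
    res = align_proteins(body, target)
    if res.identity < config.identity_threshold or res.coverage_target < 0.999:
        raise _ReconstructionFailure(
            f"reconstructed protein matches {fmap.full_length_id} at identity "
            f"{res.identity:.3f}, coverage {res.coverage_target:.3f}"
        )
    model.has_start = mrna.startswith("ATG")
    model.has_stop = True
    if len(input_ids) > 1:
        model.attributes["merged_from"] = ",".join(input_ids)

    # bridging evidence: every new seam needs a junction peptide, unless a
    # transcript chain already vouches for the whole structure
    bridging: list[str] = []
    if tier != "transcript" and new_seams:
        crossed = _crossed_offsets(model, genome, hits, config, bridging)
        missing = new_seams - crossed
        if missing:
            raise _ReconstructionFailure(
                f"no junction peptide bridges seam(s) at CDS offset(s) "
                f"{sorted(missing)} of the new structure of "
                f"{fmap.full_length_id}"
            )

    records = []
    seen_patch = False
    for p in pending:
        if p.cls == "cross_contig_patch":
            seen_patch = True
        records.append(
            CorrectionRecord(
                cls=p.cls,
                input_gene_ids=p.input_gene_ids,
                output_gene_id=model.gene_id,
                output_model=model,
                evidence=p.evidence + tuple(bridging if p.cls == "merge" else ()),
                detail=p.detail,
                evidence_tier=tier,
            )
        )
    if not seen_patch and len(model.contigs()) > 1:
        records.append(
            CorrectionRecord(
                cls="cross_contig_patch",
                input_gene_ids=tuple(input_ids),
                output_gene_id=model.gene_id,
                output_model=model,
                evidence=(f"protein:{fmap.full_length_id}",) + tuple(bridging),
                detail=f"gene spans contigs {','.join(model.contigs())}",
                evidence_tier=tier,
            )
        )
    for gid, removed in removed_by_model.items():
        spans = ",".join(f"{e.contig}:[{e.start},{e.end})" for e in removed)
        records.append(
            CorrectionRecord(
                cls="misclassified_exon_removal",
                input_gene_ids=(gid,),
                output_gene_id=model.gene_id,
                output_model=model,
                evidence=(f"protein:{fmap.full_length_id}",),
                detail=f"removed exon(s) {spans}: intronic/intergenic sequence "
                       "misannotated as coding",
                evidence_tier=tier,
            )
        )
    return model, records


def _crossed_offsets(
    model: GeneModel,
    genome: dict[str, str],
    hits: list[PeptideGenomicHit],
    config: Config,
    bridging_out: list[str],
) -> set[int]:
    """CDS offsets (nt) crossed by junction peptides on the candidate model.

    All evidence peptides are re-mapped onto the candidate; each multi-block
    occurrence contributes the cumulative offsets of its internal block
    boundaries.  A junction offset equals the offset of the exon seam the
    peptide bridges."""
    peptides = {h.peptide.sequence: h.peptide for h in hits}
    crossed: set[int] = set()
    for pep in peptides.values():
        for h in map_to_annotated(pep, [model], genome, config.il_equivalent):
            if len(h.blocks) < 2:
                continue
            pos = _cds_offset_of(model, h.blocks[0])
            if pos < 0:
                continue
            acc = pos
            for blk in h.blocks[:-1]:
                acc += len(blk)
                crossed.add(acc)
            bridging_out.append(f"peptide:{h.peptide.sequence}")
    return crossed


def _cds_offset_of(model: GeneModel, block: Exon) -> int:
    off = 0
    for e in model.exons:
        if (
            e.contig == block.contig
            and e.strand == block.strand
            and e.start <= block.start
            and block.end <= e.end
        ):
            if e.strand == "+":
                return off + (block.start - e.start)
            return off + (e.end - block.end)
        off += len(e)
    return -1


# ---------------------------------------------------------------------------
# Orchestrator


def refine_all(
    genome: dict[str, str],
    models: list[GeneModel],
    peptides: list[PeptideRecord],
    proteins: list[SeqRecord],
    transcripts: list[SeqRecord],
    config: Config | None = None,
) -> RefinementResult:
    """Run the full refinement pipeline.

    Deterministic given inputs and config, and idempotent: running the
    pipeline on its own output yields an empty ledger.
    """
    config = config or Config()
    genome = dict(genome)
    models = [replace(m, exons=list(m.exons), attributes=dict(m.attributes))
              for m in models]
    records: list[CorrectionRecord] = []
    unresolved: list[UnresolvedCase] = []

    # stage 1: integrity
    anomalies = []
    for m in models:
        anomalies.extend(check_model_integrity(m, genome))

    # stage 2: inversion detection and correction (transcript evidence)
    for tx in transcripts:
        for contig_id in list(genome):
            anom = detect_inversion(
                tx.sequence, genome[contig_id], contig_id, models, config.min_block
            )
            if anom is None:
                continue
            _, lo, hi = anom.evidence[0]
            try:
                genome, models, rec = correct_inversion(
                    genome, contig_id, (lo, hi), models,
                    evidence=(f"transcript:{tx.id}",),
                )
            except ValueError as exc:
                unresolved.append(UnresolvedCase(anom.gene_ids, str(exc)))
                continue
            anomalies.append(anom)
            records.append(rec)

    # stage 3: peptide classification against the (corrected) annotation
    orf_cache: dict[str, list[OrfHit]] = {}
    hits = classify_all(peptides, models, genome, config, orf_cache)

    # stage 4: fragment detection
    protein_seqs = {p.id: p.sequence.rstrip("*") for p in proteins}
    fmaps = detect_fragment_relation(
        models, protein_seqs, genome,
        min_identity=config.identity_threshold,
        overlap_tolerance=config.fragment_overlap_tol,
        adjacency_window=config.max_merge_gap,
    )

    # stage 5: reconstruction
    models_by_id = {m.gene_id: m for m in models}
    consumed: set[str] = set()
    final: list[GeneModel] = []
    for fmap in fmaps:
        ids = [p.gene_id for p in fmap.placements if p.gene_id not in consumed]
        if len(ids) != len(fmap.placements):
            continue  # a model already used by an earlier map
        try:
            out_model, recs = _reconstruct_one(
                fmap, models_by_id, protein_seqs[fmap.full_length_id],
                genome, orf_cache, hits, transcripts, config,
            )
        except _ReconstructionFailure as exc:
            unresolved.append(UnresolvedCase(tuple(ids), str(exc)))
            for gid in ids:
                models_by_id[gid].attributes["status"] = "putative_fragment"
            consumed.update(ids)
            final.extend(models_by_id[g] for g in ids)
            continue
        consumed.update(ids)
        if out_model is None:
            final.extend(models_by_id[g] for g in ids)
        else:
            final.append(out_model)
            records.extend(recs)

    # untouched models pass through; integrity anomalies without evidence
    # leave them flagged as putative fragments
    for m in models:
        if m.gene_id in consumed:
            continue
        if check_model_integrity(m, genome):
            m.attributes.setdefault("status", "putative_fragment")
            unresolved.append(
                UnresolvedCase(
                    (m.gene_id,),
                    "integrity anomalies but no evidence protein covers this model",
                )
            )
        final.append(m)

    # stage 6: intron retention
    proteoforms: list[ProteoformPair] = []
    ir_hits = [h for h in hits if h.category == "intron_retained"]
    retained_models: list[GeneModel] = []
    for m in final:
        mine = [h for h in ir_hits if h.gene_id == m.gene_id]
        if not mine:
            continue
        called = call_intron_retention(m, mine, genome)
        if called is None:
            unresolved.append(
                UnresolvedCase(
                    (m.gene_id,),
                    "intron-retention evidence but no stop-free in-frame "
                    "retained segment bounded by an alternative donor",
                )
            )
            continue
        pair, retained_model, rec = called
        proteoforms.append(pair)
        retained_models.append(retained_model)
        records.append(rec)
    final.extend(retained_models)

    return RefinementResult(
        genome=genome,
        models=final,
        records=records,
        unresolved=unresolved,
        hits=hits,
        proteoforms=proteoforms,
        anomalies=anomalies,
    )
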