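"""Detection of gene-annotation anomalies.

The anomaly taxonomy covers what manual curation of a fragmented draft
genome turns up: CDS integrity violations (missing start/stop, internal
stops), fragment-of-full-length relationships between annotated isoforms
and evidence proteins, transcript segments that cannot be placed on the
annotated contig (cross-contig assembly splits), and genomic blocks whose
reverse complement -- but not forward sequence -- carries the exon blocks
demanded by the evidence (inverted assembly blocks).

Alignment policy: evidence in this setting is near-identity matching, so a
single deterministic internal aligner with fixed scoring (match +2,
mismatch -1, gap open -5, gap extend -1; query global, target local)
replaces external similarity-search tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .io_formats import Exon, GeneModel
from .seqcore import STOP_CODONS, revcomp, spliced_cds

__all__ = [
    "Anomaly",
    "AlignmentResult",
    "FragmentPlacement",
    "FragmentMap",
    "TranscriptChain",
    "check_model_integrity",
    "align_proteins",
    "detect_fragment_relation",
    "spliced_align_transcript",
    "detect_inversion",
]

ANOMALY_CLASSES = frozenset(
    {
        "missing_stop",
        "internal_stop",
        "missing_start",
        "fragment_pair",
        "misclassified_exon",
        "inversion",
        "cross_contig_gap",
        "upstream_truncation",
    }
)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -1, -5, -1


@dataclass(frozen=True)
class Anomaly:
    """A typed integrity violation attached to one or more gene models."""

    gene_ids: tuple[str, ...]
    cls: str
    detail: str = ""
    evidence: tuple = ()

    def __post_init__(self) -> None:
        if self.cls not in ANOMALY_CLASSES:
            raise ValueError(f"unknown anomaly class {self.cls!r}")
        if not self.gene_ids:
            raise ValueError("anomaly must reference at least one gene")


def check_model_integrity(model: GeneModel, genome: dict[str, str]) -> list[Anomaly]:
    """CDS-level integrity checks, in fixed order: start, internal, stop."""
    mrna, protein = spliced_cds(model, genome)
    anomalies = []
    if not mrna.startswith("ATG"):
        anomalies.append(
            Anomaly((model.gene_id,), "missing_start",
                    f"CDS begins {mrna[:3]} not ATG")
        )
    body = protein[:-1] if protein.endswith("*") else protein
    if "*" in body:
        pos = body.index("*")
        anomalies.append(
            Anomaly((model.gene_id,), "internal_stop",
                    f"stop at residue {pos + 1} of {len(protein)}")
        )
    if mrna[-3:] not in STOP_CODONS or len(mrna) % 3 != 0:
        anomalies.append(
            Anomaly((model.gene_id,), "missing_stop",
                    f"CDS ends {mrna[-3:]} (length {len(mrna)})")
        )
    return anomalies


# ---------------------------------------------------------------------------
# Protein alignment


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of a query-global/target-local protein alignment."""

    identity: float
    coverage_query: float
    coverage_target: float
    target_span: tuple[int, int]  # residue interval of the target covered
    query_span: tuple[int, int]
    score: float
    n_aligned: int

    def __post_init__(self) -> None:
        for v in (self.identity, self.coverage_query, self.coverage_target):
            if not (0.0 <= v <= 1.0 + 1e-9):
                raise ValueError("fractions must lie in [0, 1]")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps in the query row = unaligned target overhangs cost nothing
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def align_proteins(query: str, target: str) -> AlignmentResult:
    """Align ``query`` (global) within ``target`` (local), fixed scoring.

    Identity is computed over aligned residue pairs, excluding terminal
    gaps.  ``target_span`` is the residue interval of the target covered by
    the query placement.
    """
    if not query or not target:
        raise ValueError("empty protein sequence")
    aln = _ALIGNER.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    n_aligned = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        n_aligned += te - ts
        matches += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
    if n_aligned == 0:
        return AlignmentResult(0.0, 0.0, 0.0, (0, 0), (0, 0), aln.score, 0)
    t_lo, t_hi = int(t_blocks[0][0]), int(t_blocks[-1][-1])
    q_lo, q_hi = int(q_blocks[0][0]), int(q_blocks[-1][-1])
    return AlignmentResult(
        identity=matches / n_aligned,
        coverage_query=n_aligned / len(query),
        coverage_target=n_aligned / len(target),
        target_span=(t_lo, t_hi),
        query_span=(q_lo, q_hi),
        score=float(aln.score),
        n_aligned=n_aligned,
    )


# ---------------------------------------------------------------------------
# Fragment-of-full-length detection


@dataclass(frozen=True)
class FragmentPlacement:
    """One annotated isoform placed as a fragment of a full-length protein."""

    gene_id: str
    target_span: tuple[int, int]
    identity: float
    coverage_query: float
    flipped: bool = False  # placement required reading the model's opposite strand


@dataclass
class FragmentMap:
    """Fragments of one full-length evidence protein, ordered along it."""

    full_length_id: str
    placements: list[FragmentPlacement]
    combined_coverage: float
    adjacent_pairs: list[tuple[str, str]] = field(default_factory=list)

    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.placements]


def model_protein(model: GeneModel, genome: dict[str, str]) -> str:
    """The protein an annotated model actually encodes, truncated at the
    first stop (ribosome semantics), trailing stop stripped."""
    _, protein = spliced_cds(model, genome)
    return protein.split("*", 1)[0]


DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_FRAGMENT_COVERAGE = 0.9
DEFAULT_OVERLAP_TOLERANCE = 5  # residues; signal-peptide/propeptide fuzz
DEFAULT_ADJACENCY_WINDOW = 50_000  # nt


def _try_place(
    protein: str, target: str, min_identity: float, min_coverage: float
) -> AlignmentResult | None:
    if len(protein) < 8:
        return None
    res = align_proteins(protein, target)
    if res.identity >= min_identity and res.coverage_query >= min_coverage:
        return res
    return None


def detect_fragment_relation(
    candidate_models: list[GeneModel],
    full_length_proteins: dict[str, str],
    genome: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_FRAGMENT_COVERAGE,
    overlap_tolerance: int = DEFAULT_OVERLAP_TOLERANCE,
    adjacency_window: int = DEFAULT_ADJACENCY_WINDOW,
) -> list[FragmentMap]:
    """Find, for each full-length protein, the annotated models that encode
    compatible near-disjoint fragments of it.

    A model whose annotated reading fails to place is retried on the
    opposite strand (a single-exon model annotated on the wrong strand is
    one of the documented anomaly classes); such placements are marked
    ``flipped``.  Placements overlapping by more than ``overlap_tolerance``
    residues are incompatible and the weaker one is dropped.
    """
    maps = []
    for fl_id, target in full_length_proteins.items():
        target = target.rstrip("*")
        placements = []
        for model in candidate_models:
            prot = model_protein(model, genome)
            res = _try_place(prot, target, min_identity, min_coverage) if prot else None
            flipped = False
            if res is None:
                flip_prot = model_protein(model.flipped(), genome)
                res = (
                    _try_place(flip_prot, target, min_identity, min_coverage)
                    if flip_prot
                    else None
                )
                flipped = res is not None
            if res is not None:
                placements.append(
                    FragmentPlacement(
                        gene_id=model.gene_id,
                        target_span=res.target_span,
                        identity=res.identity,
                        coverage_query=res.coverage_query,
                        flipped=flipped,
                    )
                )
        if not placements:
            continue
        placements.sort(key=lambda p: p.target_span)
        kept: list[FragmentPlacement] = []
        for p in placements:
            if kept:
                prev = kept[-1]
                overlap = prev.target_span[1] - p.target_span[0]
                if overlap > overlap_tolerance:
                    # incompatible overlap: keep the higher-identity, longer one
                    better = max(
                        (prev, p),
                        key=lambda x: (x.identity, x.target_span[1] - x.target_span[0]),
                    )
                    kept[-1] = better
                    continue
            kept.append(p)
        covered = sum(hi - lo for lo, hi in _merge_spans([p.target_span for p in kept]))
        by_id = {m.gene_id: m for m in candidate_models}
        adjacent = []
        for a, b in zip(kept, kept[1:]):
            ma, mb = by_id[a.gene_id], by_id[b.gene_id]
            if set(ma.contigs()) & set(mb.contigs()):
                contig = (set(ma.contigs()) & set(mb.contigs())).pop()
                sa, sb = ma.span(contig), mb.span(contig)
                gap = max(sa[0], sb[0]) - min(sa[1], sb[1])
                if gap <= adjacency_window:
                    adjacent.append((a.gene_id, b.gene_id))
            else:
                adjacent.append((a.gene_id, b.gene_id))  # bridged by the map itself
        maps.append(
            FragmentMap(
                full_length_id=fl_id,
                placements=kept,
                combined_coverage=covered / len(target),
                adjacent_pairs=adjacent,
            )
        )
    return maps


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(spans):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


# ---------------------------------------------------------------------------
# Transcript-to-genome spliced alignment


@dataclass
class TranscriptChain:
    """A co-linear exact-match chaining of an mRNA onto one contig."""

    contig: str
    strand: str
    exons: list[Exon]  # transcription order
    # mRNA segments (0-based half-open, mRNA coords) that could not be placed
    unplaced: list[tuple[int, int]]
    coverage: float  # fraction of mRNA bases placed

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        model = GeneModel("chain", self.contig, self.strand, list(self.exons))
        mrna, _ = spliced_cds(model, genome)
        return mrna


def _longest_prefix_match(query: str, text: str, lo_len: int) -> tuple[int, int]:
    """Longest prefix of ``query`` occurring in ``text``; returns (pos, length)
    with length 0 if no match of at least ``lo_len``."""
    if len(query) < lo_len or text.find(query[:lo_len]) < 0:
        return -1, 0
    lo, hi = lo_len, len(query)  # invariant: prefix of length lo matches
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if text.find(query[:mid]) >= 0:
            lo = mid
        else:
            hi = mid - 1
    return text.find(query[:lo]), lo


def _chain_one_strand(
    mrna: str, text: str, min_block: int
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int]]]:
    """Greedy co-linear chaining of mRNA onto ``text`` (forward orientation).

    Returns (blocks, unplaced) where blocks are (mrna_start, text_start, length)
    with strictly increasing text positions.
    """
    blocks = []
    unplaced = []
    i = 0
    text_pos = 0
    gap_start = None
    while i < len(mrna):
        pos, length = _longest_prefix_match(mrna[i:], text[text_pos:], min_block)
        if length >= min_block:
            if gap_start is not None:
                unplaced.append((gap_start, i))
                gap_start = None
            blocks.append((i, text_pos + pos, length))
            text_pos += pos + length
            i += length
        else:
            if gap_start is None:
                gap_start = i
            i += 1
    if gap_start is not None:
        unplaced.append((gap_start, len(mrna)))
    return blocks, unplaced


def _polish_boundaries(
    blocks: list[tuple[int, int, int]], text: str, max_shift: int = 6
) -> list[tuple[int, int, int]]:
    """Resolve splice-boundary ambiguity toward canonical GT..AG introns.

    When the end of one exact-match block could slide left while the next
    block's start slides with it (identical bases), prefer the split whose
    intron starts GT and ends AG.
    """
    blocks = [list(b) for b in blocks]
    for k in range(len(blocks) - 1):
        q0, t0, n0 = blocks[k]
        q1, t1, n1 = blocks[k + 1]
        if q0 + n0 != q1:
            continue  # an unplaced segment sits between; nothing to polish
        best = None
        for shift in range(0, max_shift + 1):
            if shift > 0:
                # move `shift` bases from end of block k to front of block k+1
                if n0 - shift < 1 or t1 - shift < 0:
                    break
                if text[t0 + n0 - shift : t0 + n0] != text[t1 - shift : t1]:
                    break
            ds, de = t0 + n0 - shift, t1 - shift  # intron interval
            if de - ds >= 4 and text[ds : ds + 2] == "GT" and text[de - 2 : de] == "AG":
                best = shift
                break
        if best:
            blocks[k][2] -= best
            blocks[k + 1][0] -= best
            blocks[k + 1][1] -= best
            blocks[k + 1][2] += best
    return [tuple(b) for b in blocks]


def spliced_align_transcript(
    mrna: str,
    contig_seq: str,
    contig_id: str = "",
    min_block: int = 20,
) -> TranscriptChain:
    """Chain an mRNA onto a contig by greedy maximal exact matching.

    Both orientations are tried; the one placing more of the mRNA wins.
    Splice boundaries are polished toward canonical GT..AG introns.
    Unplaced mRNA segments are reported (evidence of cross-contig assembly
    gaps or inverted blocks).
    """
    n = len(contig_seq)
    results = {}
    for strand in ("+", "-"):
        text = contig_seq if strand == "+" else revcomp(contig_seq)
        blocks, unplaced = _chain_one_strand(mrna, text, min_block)
        blocks = _polish_boundaries(blocks, text)
        placed = sum(b[2] for b in blocks)
        results[strand] = (blocks, unplaced, placed, text)
    strand = max(results, key=lambda s: results[s][2])
    blocks, unplaced, placed, text = results[strand]
    exons = []
    for _, t_start, length in blocks:
        if strand == "+":
            gs, ge = t_start, t_start + length
        else:
            gs, ge = n - (t_start + length), n - t_start
        exons.append(Exon(contig=contig_id, start=gs, end=ge, strand=strand))
    return TranscriptChain(
        contig=contig_id,
        strand=strand,
        exons=exons,
        unplaced=unplaced,
        coverage=placed / len(mrna) if mrna else 0.0,
    )


# ---------------------------------------------------------------------------
# Inversion detection


def detect_inversion(
    mrna: str,
    contig_seq: str,
    contig_id: str = "",
    models: list[GeneModel] | None = None,
    min_block: int = 20,
) -> Anomaly | None:
    """Flag a genomic interval whose reverse complement -- but not forward
    sequence -- carries exon blocks required by the transcript evidence,
    while flanking blocks map in the forward orientation.

    Returns an ``inversion`` anomaly carrying the breakpoint interval in its
    evidence, or None if the transcript is consistent with the contig.
    """
    chain = spliced_align_transcript(mrna, contig_seq, contig_id, min_block)
    if chain.coverage >= 0.999 or not chain.unplaced:
        return None
    n = len(contig_seq)
    flipped_spans = []
    for q_lo, q_hi in chain.unplaced:
        segment = mrna[q_lo:q_hi]
        if len(segment) < min_block:
            continue
        # the segment must chain on the orientation opposite the main chain
        text = revcomp(contig_seq) if chain.strand == "+" else contig_seq
        blocks, seg_unplaced = _chain_one_strand(segment, text, min_block)
        placed = sum(b[2] for b in blocks)
        if placed < 0.95 * len(segment):
            continue
        for _, t_start, length in blocks:
            if chain.strand == "+":
                gs, ge = n - (t_start + length), n - t_start
            else:
                gs, ge = t_start, t_start + length
            flipped_spans.append((gs, ge))
    if not flipped_spans:
        return None
    lo = min(s for s, _ in flipped_spans)
    hi = max(e for _, e in flipped_spans)
    gene_ids = tuple(
        m.gene_id
        for m in (models or [])
        if m.contig == contig_id and m.span()[0] < hi and lo < m.span()[1]
    ) or ("unannotated",)
    return Anomaly(
        gene_ids=gene_ids,
        cls="inversion",
        detail=f"{contig_id}:[{lo},{hi}) maps only in reverse orientation",
        evidence=((contig_id, lo, hi),),
    )
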