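"""Deterministic sequence primitives.

Translation (standard genetic code; N-containing codons become ``X``),
spliced CDS assembly over per-exon contig/strand, in-silico tryptic
digestion, six-frame ORF scanning and canonical GT/AG splice-site
discovery.  Everything here is pure string arithmetic on the 0-based
half-open intervals used package-wide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data import CodonTable
from pyteomics import parser as _pyt_parser

__all__ = [
    "STOP_CODONS",
    "revcomp",
    "translate",
    "spliced_cds",
    "tryptic_digest",
    "tryptic_digest_positions",
    "OrfHit",
    "six_frame_scan",
    "SpliceSite",
    "find_splice_sites",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_MAP: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA
for _stop in STOP_CODONS:
    CODON_MAP[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRYPSIN_RULE = _pyt_parser.expasy_rules["trypsin"]  # cleave after K/R, not before P


def revcomp(dna: str) -> str:
    """Reverse complement (A<->T, C<->G, N->N)."""
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, offset: int = 0) -> str:
    """Translate ``dna`` from ``offset`` with the standard genetic code.

    Trailing partial codons are dropped; stop codons render ``*`` and any
    codon containing N renders ``X`` (no ambiguity resolution, so assembly
    gaps never fabricate residues).
    """
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    out = []
    for i in range(offset, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        aa = CODON_MAP.get(codon)
        if aa is None:
            aa = "X"
        out.append(aa)
    return "".join(out)


def spliced_cds(model, genome: dict[str, str]) -> tuple[str, str]:
    """Assemble the spliced CDS of a gene model and translate it.

    Exon sequences are extracted per exon from that exon's own contig and
    strand (minus-strand blocks are reverse-complemented), then concatenated
    in transcription order.  Returns ``(mrna, protein)``.
    """
    pieces = []
    for exon in model.exons:
        if exon.contig not in genome:
            raise ValueError(f"unknown contig {exon.contig}")
        contig = genome[exon.contig]
        if exon.end > len(contig):
            raise ValueError(
                f"exon [{exon.start},{exon.end}) out of bounds on {exon.contig}"
            )
        seq = contig[exon.start : exon.end]
        pieces.append(revcomp(seq) if exon.strand == "-" else seq)
    mrna = "".join(pieces)
    return mrna, translate(mrna)


def tryptic_digest_positions(
    protein: str,
    missed_cleavages: int = 2,
    min_len: int = 7,
    max_len: int = 35,
) -> list[tuple[int, str]]:
    """Tryptic peptides with their start positions, sorted by (start, length).

    The rule is the classical one: cleave C-terminal to K or R except when
    the next residue is P.  All products with up to ``missed_cleavages``
    internal uncleaved sites are emitted, filtered to [min_len, max_len].
    """
    if "*" in protein:
        raise ValueError("protein must not contain stop characters")
    cut_after = [m.end() for m in re.finditer(TRYPSIN_RULE, protein)]
    boundaries = [0] + cut_after
    if not boundaries or boundaries[-1] != len(protein):
        boundaries.append(len(protein))
    out = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            if min_len <= end - start <= max_len:
                out.append((start, protein[start:end]))
    out.sort(key=lambda t: (t[0], len(t[1])))
    return out


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 2,
    min_len: int = 7,
    max_len: int = 35,
) -> list[str]:
    """Tryptic peptide sequences (see :func:`tryptic_digest_positions`)."""
    return [p for _, p in tryptic_digest_positions(protein, missed_cleavages, min_len, max_len)]


@dataclass(frozen=True)
class OrfHit:
    """A maximal stop-free translated stretch with its genomic projection."""

    contig: str
    strand: str
    frame: int
    start: int  # genomic, 0-based half-open, forward coordinates
    end: int
    protein: str

    def __post_init__(self) -> None:
        if self.end - self.start != 3 * len(self.protein):
            raise ValueError("ORF genomic span must be 3x protein length")


def six_frame_scan(
    contig_seq: str, min_protein_len: int = 8, contig_id: str = ""
) -> list[OrfHit]:
    """All maximal stop-free translated stretches in all six reading frames.

    Equivalent to translating each frame and splitting on ``*``; stretches
    shorter than ``min_protein_len`` are dropped.  Stretches may start at
    any codon (no ATG requirement): the scan is a search space for peptide
    evidence, not a gene finder.
    """
    n = len(contig_seq)
    hits = []
    for strand in ("+", "-"):
        seq = contig_seq if strand == "+" else revcomp(contig_seq)
        for frame in range(3):
            prot = translate(seq, frame)
            pos = 0
            for stretch in prot.split("*"):
                if len(stretch) >= min_protein_len:
                    # local coords on `seq`
                    s = frame + 3 * pos
                    e = s + 3 * len(stretch)
                    if strand == "+":
                        gs, ge = s, e
                    else:
                        gs, ge = n - e, n - s
                    hits.append(
                        OrfHit(
                            contig=contig_id,
                            strand=strand,
                            frame=frame,
                            start=gs,
                            end=ge,
                            protein=stretch,
                        )
                    )
                pos += len(stretch) + 1
    return hits


@dataclass(frozen=True)
class SpliceSite:
    """A canonical splice dinucleotide, coding-strand oriented.

    ``position`` is the 0-based genomic index of the first intronic base for
    a donor and of the last intronic base for an acceptor.
    """

    contig: str
    strand: str
    position: int
    kind: str  # donor | acceptor


def find_splice_sites(
    contig_seq: str,
    window: tuple[int, int] | None = None,
    contig_id: str = "",
) -> list[SpliceSite]:
    """All canonical GT donors and AG acceptors on both strands in a window.

    On the plus strand an intron reads GT...AG left to right; on the minus
    strand the coding-strand GT...AG appears as CT...AC pairs (AC = donor
    seen from the right, CT = acceptor).
    """
    lo, hi = window if window is not None else (0, len(contig_seq))
    lo, hi = max(0, lo), min(len(contig_seq), hi)
    region = contig_seq[lo:hi]
    sites = []
    for m in re.finditer("(?=GT)", region):
        sites.append(SpliceSite(contig_id, "+", lo + m.start(), "donor"))
    for m in re.finditer("(?=AG)", region):
        sites.append(SpliceSite(contig_id, "+", lo + m.start() + 1, "acceptor"))
    # minus strand: plus-strand "AC" at [p, p+2) is coding-strand GT whose
    # first intronic base (5' of the intron on minus) is plus-index p+1
    for m in re.finditer("(?=AC)", region):
        sites.append(SpliceSite(contig_id, "-", lo + m.start() + 1, "donor"))
    for m in re.finditer("(?=CT)", region):
        sites.append(SpliceSite(contig_id, "-", lo + m.start(), "acceptor"))
    sites.sort(key=lambda s: (s.position, s.strand, s.kind))
    return sites
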