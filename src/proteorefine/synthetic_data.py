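"""Synthetic genomes with known-true gene models and injected anomalies.

Each scenario builds a small multi-contig genome around one protease-like
gene, then corrupts the annotation (never the truth) the way fragmented
draft-genome annotations are corrupted in practice:

==========  ==============================================================
 scenario    injected anomaly
==========  ==============================================================
 A           gene split in two; one internal exon unannotated (intergenic);
             the 3' fragment annotated on the wrong strand
 B           terminal exon physically split across contigs (assembly gap)
 C           true terminal exon unannotated; an intronic stretch
             misannotated as the last exon; stop codon lost
 D           gene split in three across two contigs
 E           adjacent fragments on one contig, one internal exon
             unannotated, terminal exon on another contig
 F           genomic block reverse-complemented (inversion); the block's
             exons annotated as a separate plus-strand gene
 G           two 5' exons unannotated (truncated upstream)
 H           annotation correct, but the expressed proteoforms include an
             intron-retention variant (alternative donor, in-frame)
==========  ==============================================================

Evidence (tryptic peptides, transcripts, full-length proteins) is sampled
from the truth so that every scenario's correction is recoverable, and the
generator verifies recoverability structurally (junction peptides exist,
gap segments are unique in six-frame space, transcript chains reproduce
the truth exons) before a bundle is returned.  All randomness flows from a
single integer seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .anomaly_detection import detect_inversion, spliced_align_transcript
from .io_formats import Exon, GeneModel, PeptideRecord, SeqRecord
from .seqcore import (
    STOP_CODONS,
    revcomp,
    six_frame_scan,
    spliced_cds,
    translate,
    tryptic_digest,
    tryptic_digest_positions,
)

__all__ = [
    "Scenario",
    "ScenarioBundle",
    "SCENARIO_CLASSES",
    "generate_gene",
    "generate_scenario",
    "generate_bundle",
]

SCENARIO_CLASSES = "ABCDEFGH"

_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# one fixed codon per residue, for engineered stretches
_AA_CODON = {}
for _c in _NONSTOP_CODONS:
    _aa = translate(_c)
    _AA_CODON.setdefault(_aa, _c)

_SAFE_AA = "ADEFGHNQSTVWY"  # no K/R (tryptic sites), no P, no I/L ambiguity


def _rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _rand_codons(rng: random.Random, n: int) -> str:
    """n random non-stop codons (rejection-free: sampled from the 61)."""
    return "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n))


def _make_intron(rng: random.Random, length: int) -> str:
    if length < 8:
        raise ValueError("intron too short")
    return "GT" + _rand_dna(rng, length - 4) + "AG"


def _random_cds(rng: random.Random, n_codons: int) -> str:
    if n_codons < 3:
        raise ValueError("CDS needs >= 3 codons")
    return "ATG" + _rand_codons(rng, n_codons - 2) + rng.choice(sorted(STOP_CODONS))


@dataclass
class _Layout:
    """A gene laid out on a plus-strand contig before strand application."""

    seq: str
    exons: list[tuple[int, int]]  # plus coords, one per exon, ascending
    cds: str


def _build_layout(
    rng: random.Random,
    exon_codons: list[int],
    intron_lens: list[int],
    pad5: int,
    pad3: int,
    cds: str | None = None,
    introns: list[str] | None = None,
) -> _Layout:
    total = sum(exon_codons)
    if cds is None:
        cds = _random_cds(rng, total)
    assert len(cds) == 3 * total
    if introns is None:
        introns = [_make_intron(rng, n) for n in intron_lens]
    assert len(introns) == len(exon_codons) - 1
    pieces = [_rand_dna(rng, pad5)]
    cursor = pad5
    exons = []
    cds_pos = 0
    for i, n in enumerate(exon_codons):
        chunk = cds[cds_pos : cds_pos + 3 * n]
        cds_pos += 3 * n
        pieces.append(chunk)
        exons.append((cursor, cursor + len(chunk)))
        cursor += len(chunk)
        if i < len(introns):
            pieces.append(introns[i])
            cursor += len(introns[i])
    pieces.append(_rand_dna(rng, pad3))
    return _Layout(seq="".join(pieces), exons=exons, cds=cds)


def _strand_exons(
    layout: _Layout, contig_id: str, strand: str
) -> tuple[str, list[Exon]]:
    """Apply a strand to a plus layout; exon list stays in transcription order."""
    if strand == "+":
        seq = layout.seq
        exons = [Exon(contig_id, s, e, "+") for s, e in layout.exons]
    else:
        L = len(layout.seq)
        seq = revcomp(layout.seq)
        exons = [Exon(contig_id, L - e, L - s, "-") for s, e in layout.exons]
    return seq, exons


def generate_gene(
    seed: int,
    n_exons: int,
    exon_len_range: tuple[int, int] = (13, 25),
    intron_len_range: tuple[int, int] = (60, 120),
    strand: str = "+",
    contig_id: str = "ctg1",
    gene_id: str = "gene1",
) -> tuple[SeqRecord, GeneModel, str]:
    """One random gene on one contig: ATG start, clean stop, GT..AG introns.

    Exon lengths are drawn in codons (boundaries are codon-aligned), so the
    spliced CDS is trivially in frame.  Deterministic given the seed.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    rng = random.Random(seed)
    exon_codons = [rng.randint(*exon_len_range) for _ in range(n_exons)]
    intron_lens = [rng.randint(*intron_len_range) for _ in range(n_exons - 1)]
    layout = _build_layout(rng, exon_codons, intron_lens,
                           rng.randint(520, 640), rng.randint(520, 640))
    seq, exons = _strand_exons(layout, contig_id, strand)
    model = GeneModel(gene_id, contig_id, strand, exons)
    protein = translate(layout.cds)[:-1]
    return SeqRecord(contig_id, seq), model, protein


# ---------------------------------------------------------------------------
# Evidence helpers


def _junction_peptide(
    protein: str, seam: int, mc: int = 2, min_len: int = 7, max_len: int = 35
) -> str | None:
    """Shortest tryptic peptide covering residues seam-1 and seam."""
    best = None
    for s, p in tryptic_digest_positions(protein, mc, min_len, max_len):
        if s <= seam - 1 and s + len(p) >= seam + 1:
            if best is None or len(p) < len(best):
                best = p
    return best


def _internal_peptide(
    protein: str, lo: int, hi: int, mc: int = 2, min_len: int = 7, max_len: int = 35
) -> str | None:
    """A tryptic peptide lying fully inside the residue interval [lo, hi)."""
    best = None
    for s, p in tryptic_digest_positions(protein, mc, min_len, max_len):
        if s >= lo and s + len(p) <= hi:
            if best is None or len(p) > len(best):
                best = p  # prefer the longest: stronger exon support
    return best


def _base_peptides(rng: random.Random, protein: str) -> list[str]:
    return tryptic_digest(protein, missed_cleavages=0, min_len=7, max_len=35)


@dataclass
class Scenario:
    name: str
    genome: dict[str, str]
    truth_models: list[GeneModel]
    corrupted_models: list[GeneModel]
    protein: SeqRecord
    transcripts: list[SeqRecord]
    peptides: list[PeptideRecord]
    required_peptides: list[str]
    expected_records: list[tuple[str, tuple[str, ...]]]
    expected_anomalies: dict[str, list[str]]
    gap_segments: list[str] = field(default_factory=list)
    # required peptides that must be findable (exactly once) in six-frame
    # genomic space: exon-internal and intron-boundary peptides.  The other
    # required peptides are junction peptides, which span introns and are
    # deliberately absent from six-frame space.
    genomic_peptides: list[str] = field(default_factory=list)


class _BuildFailure(Exception):
    """The random draw cannot satisfy the scenario's evidence guarantees."""


def _finish_peptides(
    rng: random.Random, scenario: Scenario, extra: list[str]
) -> None:
    seqs: list[str] = []
    for p in _base_peptides(rng, scenario.protein.sequence) + extra:
        if p not in seqs:
            seqs.append(p)
    scenario.peptides = [
        PeptideRecord(p, rng.randint(1, 30), "synthetic") for p in seqs
    ]


def _cum(exon_codons: list[int], k: int) -> int:
    return sum(exon_codons[:k])


# ---------------------------------------------------------------------------
# Scenario builders


def _scenario_A(seed: int) -> Scenario:
    """Split gene + hidden intergenic exon + wrong-strand 3' fragment."""
    rng = random.Random(seed)
    codons = [15, 14, 13, 15, 14, 13, 15, 26, 16]
    introns = [rng.randint(70, 120) for _ in range(8)]
    layout = _build_layout(rng, codons, introns,
                           rng.randint(520, 640), rng.randint(520, 640))
    contig = "ctgA1"
    seq, exons = _strand_exons(layout, contig, "+")
    protein = translate(layout.cds)[:-1]
    truth = GeneModel("geneA1-geneA2", contig, "+", exons)
    g1 = GeneModel("geneA1", contig, "+", exons[:7], has_stop=False)
    # 3' fragment annotated on the wrong strand (single exon)
    e9 = exons[8]
    g2 = GeneModel(
        "geneA2", contig, "-", [Exon(contig, e9.start, e9.end, "-")],
        has_start=False,
    )
    seam78, seam89 = _cum(codons, 7), _cum(codons, 8)
    j78 = _junction_peptide(protein, seam78)
    j89 = _junction_peptide(protein, seam89)
    inner = _internal_peptide(protein, seam78, seam89)
    if not (j78 and j89 and inner):
        raise _BuildFailure("no junction/internal peptides for scenario A")
    scen = Scenario(
        name="A",
        genome={contig: seq},
        truth_models=[truth],
        corrupted_models=[g1, g2],
        protein=SeqRecord("protA", protein),
        transcripts=[],
        peptides=[],
        required_peptides=[j78, j89, inner],
        genomic_peptides=[inner],
        expected_records=[
            ("novel_exon", ("geneA1", "geneA2")),
            ("merge", ("geneA1", "geneA2")),
        ],
        expected_anomalies={"geneA1": ["missing_stop"]},
        gap_segments=[protein[seam78:seam89]],
    )
    _finish_peptides(rng, scen, [j78, j89, inner])
    return scen


def _scenario_B(seed: int) -> Scenario:
    """Terminal exon physically split across contigs (minus strand)."""
    rng = random.Random(seed)
    codons = [20, 30, 30, 40]
    split = 22  # codons of exon 4 kept on the main contig
    introns = [rng.randint(70, 120) for _ in range(3)]
    cds = _random_cds(rng, sum(codons))
    # main contig carries exons 1-3 and the first `split` codons of exon 4
    main_codons = codons[:3] + [split]
    main_cds = cds[: 3 * sum(main_codons)]
    lay_main = _build_layout(
        rng, main_codons, introns, rng.randint(520, 640), rng.randint(520, 640),
        cds=main_cds,
    )
    rest = cds[3 * sum(main_codons):]
    lay_donor = _Layout(
        seq=_rand_dna(rng, 420) + rest + _rand_dna(rng, 420),
        exons=[(420, 420 + len(rest))],
        cds=rest,
    )
    main_seq, main_exons = _strand_exons(lay_main, "ctgB1", "-")
    donor_seq, donor_exons = _strand_exons(lay_donor, "ctgB2", "-")
    protein = translate(cds)[:-1]
    truth = GeneModel("geneB1", "ctgB1", "-", main_exons + donor_exons)
    corrupt = GeneModel("geneB1", "ctgB1", "-", list(main_exons), has_stop=False)
    seam = _cum(codons, 3) + split
    j = _junction_peptide(protein, seam)
    if not j:
        raise _BuildFailure("no split-spanning peptide for scenario B")
    scen = Scenario(
        name="B",
        genome={"ctgB1": main_seq, "ctgB2": donor_seq},
        truth_models=[truth],
        corrupted_models=[corrupt],
        protein=SeqRecord("protB", protein),
        transcripts=[],
        peptides=[],
        required_peptides=[j],
        expected_records=[("cross_contig_patch", ("geneB1",))],
        expected_anomalies={"geneB1": ["missing_stop"]},
        gap_segments=[protein[seam:]],
    )
    _finish_peptides(rng, scen, [j])
    return scen


def _scenario_C(seed: int) -> Scenario:
    """Missing terminal exon + intronic stretch misannotated as an exon."""
    rng = random.Random(seed)
    codons = [15, 14, 13, 15, 14, 13, 15, 20, 18]
    introns = [rng.randint(70, 120) for _ in range(8)]
    # intron 8 hosts the fake "ninth exon": a stretch beginning with an
    # in-frame stop so the misannotation truncates the protein immediately
    fake_len = 12
    i8 = introns[7] = max(introns[7], 60) + fake_len
    fake_offset = 20  # nt into intron 8
    fake_seq = "TAA" + _rand_codons(rng, fake_len // 3 - 1)
    intron8 = (
        "GT"
        + _rand_dna(rng, fake_offset - 2)
        + fake_seq
        + _rand_dna(rng, i8 - fake_offset - fake_len - 2)
        + "AG"
    )
    intron_seqs = [_make_intron(rng, n) for n in introns[:7]] + [intron8]
    layout = _build_layout(
        rng, codons, introns, rng.randint(520, 640), rng.randint(520, 640),
        introns=intron_seqs,
    )
    contig = "ctgC1"
    seq, exons = _strand_exons(layout, contig, "+")
    protein = translate(layout.cds)[:-1]
    truth = GeneModel("geneC1", contig, "+", exons)
    fake_start = exons[7].end + fake_offset
    fake_exon = Exon(contig, fake_start, fake_start + fake_len, "+")
    corrupt = GeneModel("geneC1", contig, "+", exons[:8] + [fake_exon])
    seam89 = _cum(codons, 8)
    j89 = _junction_peptide(protein, seam89)
    inner = _internal_peptide(protein, seam89, len(protein))
    if not (j89 and inner):
        raise _BuildFailure("no junction/terminal peptides for scenario C")
    scen = Scenario(
        name="C",
        genome={contig: seq},
        truth_models=[truth],
        corrupted_models=[corrupt],
        protein=SeqRecord("protC", protein),
        transcripts=[],
        peptides=[],
        required_peptides=[j89, inner],
        genomic_peptides=[inner],
        expected_records=[
            ("terminal_exon_addition", ("geneC1",)),
            ("misclassified_exon_removal", ("geneC1",)),
        ],
        expected_anomalies={"geneC1": ["internal_stop", "missing_stop"]},
        gap_segments=[protein[seam89:]],
    )
    _finish_peptides(rng, scen, [j89, inner])
    return scen


def _scenario_D(seed: int) -> Scenario:
    """Three-way split across two contigs."""
    rng = random.Random(seed)
    codons = [16, 20, 18, 15, 15, 16]
    cds = _random_cds(rng, sum(codons))
    cds1 = cds[: 3 * sum(codons[:2])]
    cds2 = cds[3 * sum(codons[:2]):]
    lay1 = _build_layout(
        rng, codons[:2], [rng.randint(70, 120)],
        rng.randint(520, 640), rng.randint(520, 640), cds=cds1,
    )
    lay2 = _build_layout(
        rng, codons[2:], [rng.randint(70, 120) for _ in range(3)],
        rng.randint(520, 640), rng.randint(520, 640), cds=cds2,
    )
    seq1, exons1 = _strand_exons(lay1, "ctgD1", "+")
    seq2, exons2 = _strand_exons(lay2, "ctgD2", "+")
    protein = translate(cds)[:-1]
    for k in (2, 3):  # fragment 5' ends must visibly lack a start codon
        if cds[3 * _cum(codons, k) : 3 * _cum(codons, k) + 3] == "ATG":
            raise _BuildFailure("fragment starts with ATG by chance")
    truth = GeneModel("geneD1-geneD2-geneD3", "ctgD1", "+", exons1 + exons2)
    f1 = GeneModel("geneD1", "ctgD1", "+", list(exons1), has_stop=False)
    f2 = GeneModel("geneD2", "ctgD2", "+", [exons2[0]],
                   has_start=False, has_stop=False)
    f3 = GeneModel("geneD3", "ctgD2", "+", exons2[1:], has_start=False)
    seam23, seam34 = _cum(codons, 2), _cum(codons, 3)
    j23 = _junction_peptide(protein, seam23)
    j34 = _junction_peptide(protein, seam34)
    if not (j23 and j34):
        raise _BuildFailure("no seam peptides for scenario D")
    ids = ("geneD1", "geneD2", "geneD3")
    scen = Scenario(
        name="D",
        genome={"ctgD1": seq1, "ctgD2": seq2},
        truth_models=[truth],
        corrupted_models=[f1, f2, f3],
        protein=SeqRecord("protD", protein),
        transcripts=[],
        peptides=[],
        required_peptides=[j23, j34],
        expected_records=[("merge", ids), ("cross_contig_patch", ids)],
        expected_anomalies={
            "geneD1": ["missing_stop"],
            "geneD2": ["missing_start", "missing_stop"],
            "geneD3": ["missing_start"],
        },
    )
    _finish_peptides(rng, scen, [j23, j34])
    return scen


def _scenario_E(seed: int) -> Scenario:
    """Adjacent fragments + hidden internal exon + terminal exon elsewhere."""
    rng = random.Random(seed)
    codons = [15, 16, 14, 24, 15, 14, 16]
    cds = _random_cds(rng, sum(codons))
    main_cds = cds[: 3 * sum(codons[:6])]
    lay_main = _build_layout(
        rng, codons[:6], [rng.randint(70, 120) for _ in range(5)],
        rng.randint(520, 640), rng.randint(520, 640), cds=main_cds,
    )
    rest = cds[3 * sum(codons[:6]):]
    lay_donor = _Layout(
        seq=_rand_dna(rng, 420) + rest + _rand_dna(rng, 420),
        exons=[(420, 420 + len(rest))],
        cds=rest,
    )
    main_seq, main_exons = _strand_exons(lay_main, "ctgE1", "-")
    donor_seq, donor_exons = _strand_exons(lay_donor, "ctgE2", "-")
    protein = translate(cds)[:-1]
    if cds[3 * _cum(codons, 4) : 3 * _cum(codons, 4) + 3] == "ATG":
        raise _BuildFailure("fragment starts with ATG by chance")
    truth = GeneModel("geneE1-geneE2", "ctgE1", "-", main_exons + donor_exons)
    g1 = GeneModel("geneE1", "ctgE1", "-", main_exons[:3], has_stop=False)
    g2 = GeneModel("geneE2", "ctgE1", "-", main_exons[4:6],
                   has_start=False, has_stop=False)
    seam34, seam45, seam67 = _cum(codons, 3), _cum(codons, 4), _cum(codons, 6)
    j34 = _junction_peptide(protein, seam34)
    j45 = _junction_peptide(protein, seam45)
    j67 = _junction_peptide(protein, seam67)
    inner = _internal_peptide(protein, seam34, seam45)
    if not (j34 and j45 and j67 and inner):
        raise _BuildFailure("no seam/internal peptides for scenario E")
    ids = ("geneE1", "geneE2")
    scen = Scenario(
        name="E",
        genome={"ctgE1": main_seq, "ctgE2": donor_seq},
        truth_models=[truth],
        corrupted_models=[g1, g2],
        protein=SeqRecord("protE", protein),
        transcripts=[],
        peptides=[],
        required_peptides=[j34, j45, j67, inner],
        genomic_peptides=[inner],
        expected_records=[
            ("novel_exon", ids),
            ("merge", ids),
            ("cross_contig_patch", ids),
        ],
        expected_anomalies={
            "geneE1": ["missing_stop"],
            "geneE2": ["missing_start", "missing_stop"],
        },
        gap_segments=[protein[seam34:seam45], protein[seam67:]],
    )
    _finish_peptides(rng, scen, [j34, j45, j67, inner])
    return scen


def _scenario_F(seed: int) -> Scenario:
    """Inverted genomic block; its exons annotated as a plus-strand gene.

    The truth gene sits on the minus strand.  Exons 4-7 (the C-terminal
    half) fall inside a block that the assembly reverse-complemented, so in
    the released genome they read on the plus strand; the annotation
    reflects that as a separate plus-strand fragment gene.  No peptides:
    this case is recovered through transcript evidence alone.
    """
    rng = random.Random(seed)
    # the un-inverted half must carry the majority of the mRNA, otherwise
    # orientation of the inversion is ambiguous from transcript evidence
    codons = [24, 25, 23, 13, 14, 12, 15]
    introns = [rng.randint(70, 120) for _ in range(6)]
    layout = _build_layout(rng, codons, introns,
                           rng.randint(520, 640), rng.randint(520, 640))
    contig = "ctgF1"
    virtual_seq, virtual_exons = _strand_exons(layout, contig, "-")
    protein = translate(layout.cds)[:-1]
    if layout.cds[3 * _cum(codons, 3) : 3 * _cum(codons, 3) + 3] == "ATG":
        raise _BuildFailure("fragment starts with ATG by chance")
    # the inverted block spans exons 4..7 exactly (minus gene: genomic left)
    block = virtual_exons[3:7]
    lo = min(e.start for e in block)
    hi = max(e.end for e in block)
    emitted_seq = virtual_seq[:lo] + revcomp(virtual_seq[lo:hi]) + virtual_seq[hi:]

    def _remap(e: Exon) -> Exon:
        return Exon(contig, lo + hi - e.end, lo + hi - e.start,
                    "+" if e.strand == "-" else "-")

    truth_exons = virtual_exons[:3] + [_remap(e) for e in virtual_exons[3:]]
    truth = GeneModel("geneF1-geneF2", contig, "-", truth_exons)
    g1 = GeneModel("geneF1", contig, "-", virtual_exons[:3], has_stop=False)
    g2 = GeneModel("geneF2", contig, "+",
                   [_remap(e) for e in virtual_exons[3:]], has_start=False)
    mrna = layout.cds
    tx = SeqRecord("txF", mrna)
    # structural verification: the inversion must be exactly recoverable and
    # the transcript chain must reproduce the truth exons on the virtual seq
    anom = detect_inversion(mrna, emitted_seq, contig, [g1, g2])
    if anom is None or anom.evidence[0][1:] != (lo, hi):
        raise _BuildFailure("inversion interval not exactly recoverable")
    chain = spliced_align_transcript(mrna, virtual_seq, contig)
    if [(e.start, e.end) for e in chain.exons] != [
        (e.start, e.end) for e in virtual_exons
    ]:
        raise _BuildFailure("transcript chain does not reproduce truth exons")
    scen = Scenario(
        name="F",
        genome={contig: emitted_seq},
        truth_models=[truth],
        corrupted_models=[g1, g2],
        protein=SeqRecord("protF", protein),
        transcripts=[tx],
        peptides=[],
        required_peptides=[],
        expected_records=[
            ("inversion_fix", ("geneF2",)),
            ("merge", ("geneF1", "geneF2")),
        ],
        expected_anomalies={
            "geneF1": ["missing_stop"],
            "geneF2": ["missing_start"],
        },
    )
    scen.peptides = []
    return scen


def _scenario_G(seed: int) -> Scenario:
    """Two 5' exons unannotated; recovered from the transcript chain."""
    rng = random.Random(seed)
    codons = [14, 15, 16, 15, 14, 15, 16, 15]
    introns = [rng.randint(70, 120) for _ in range(7)]
    layout = _build_layout(rng, codons, introns,
                           rng.randint(520, 640), rng.randint(520, 640))
    contig = "ctgG1"
    seq, exons = _strand_exons(layout, contig, "+")
    protein = translate(layout.cds)[:-1]
    if layout.cds[3 * _cum(codons, 2) : 3 * _cum(codons, 2) + 3] == "ATG":
        # the truncated model must visibly lack a start codon
        raise _BuildFailure("exon 3 starts with ATG by chance")
    truth = GeneModel("geneG1", contig, "+", exons)
    corrupt = GeneModel("geneG1", contig, "+", exons[2:], has_start=False)
    tx = SeqRecord("txG", layout.cds)
    chain = spliced_align_transcript(layout.cds, seq, contig)
    if [(e.start, e.end) for e in chain.exons] != [
        (e.start, e.end) for e in exons
    ]:
        raise _BuildFailure("transcript chain does not reproduce truth exons")
    scen = Scenario(
        name="G",
        genome={contig: seq},
        truth_models=[truth],
        corrupted_models=[corrupt],
        protein=SeqRecord("protG", protein),
        transcripts=[tx],
        peptides=[],
        required_peptides=[],
        expected_records=[("upstream_exon_addition", ("geneG1",))],
        expected_anomalies={"geneG1": ["missing_start"]},
    )
    return scen


def _scenario_H(seed: int) -> Scenario:
    """Intron retention: an alternative donor 21 nt into intron 2 yields a
    proteoform with 7 extra residues; a tryptic peptide spans the exon-2 /
    retained-intron junction."""
    rng = random.Random(seed)
    codons = [18, 22, 20, 16]
    # exon 2 tail: a K cut site then 9 safe residues, so the boundary
    # peptide is exactly (9 exon residues + 7 retained residues)
    tail_aa = "K" + "".join(rng.choice(_SAFE_AA) for _ in range(9))
    tail = "".join(_AA_CODON[a] for a in tail_aa)
    cds_head = "ATG" + _rand_codons(rng, codons[0] - 1)
    exon2_body = _rand_codons(rng, codons[1] - len(tail_aa))
    cds_rest = _rand_codons(rng, codons[2] + codons[3] - 1) + rng.choice(
        sorted(STOP_CODONS)
    )
    cds = cds_head + exon2_body + tail + cds_rest
    # retained segment: 7 codons, starts GT (the canonical donor), ends K
    retained_aa = "V" + "".join(rng.choice(_SAFE_AA) for _ in range(5)) + "K"
    retained = "".join(_AA_CODON[a] for a in retained_aa)
    assert retained.startswith("GT")
    # after the retained prefix: alternative donor GT, then an in-frame stop
    # at offset 24 so no longer stop-free prefix can out-compete L=21
    intron2 = retained + "GT" + rng.choice("ACGT") + "TAA" + _rand_dna(
        rng, rng.randint(50, 80)
    ) + "AG"
    intron_seqs = [
        _make_intron(rng, rng.randint(70, 120)),
        intron2,
        _make_intron(rng, rng.randint(70, 120)),
    ]
    layout = _build_layout(
        rng, codons, [len(s) for s in intron_seqs],
        rng.randint(520, 640), rng.randint(520, 640),
        cds=cds, introns=intron_seqs,
    )
    contig = "ctgH1"
    seq, exons = _strand_exons(layout, contig, "+")
    protein = translate(cds)[:-1]
    truth = GeneModel("geneH1", contig, "+", exons)
    corrupt = GeneModel("geneH1", contig, "+", list(exons))
    seam2 = _cum(codons, 2)
    retained_protein = protein[:seam2] + retained_aa + protein[seam2:]
    boundary_pep = tail_aa[1:] + retained_aa  # 9 exon + 7 retained residues
    if boundary_pep not in tryptic_digest(retained_protein, 0, 7, 35):
        raise _BuildFailure("boundary peptide is not a clean tryptic product")
    if boundary_pep in tryptic_digest(protein, 2, 7, 35):
        raise _BuildFailure("boundary peptide collides with canonical digest")
    scen = Scenario(
        name="H",
        genome={contig: seq},
        truth_models=[truth],
        corrupted_models=[corrupt],
        protein=SeqRecord("protH", protein),
        transcripts=[],
        peptides=[],
        required_peptides=[boundary_pep],
        genomic_peptides=[boundary_pep],
        expected_records=[("intron_retention", ("geneH1",))],
        expected_anomalies={},
    )
    _finish_peptides(rng, scen, [boundary_pep])
    return scen


_BUILDERS = {
    "A": _scenario_A,
    "B": _scenario_B,
    "C": _scenario_C,
    "D": _scenario_D,
    "E": _scenario_E,
    "F": _scenario_F,
    "G": _scenario_G,
    "H": _scenario_H,
}


def _verify_scenario(scen: Scenario) -> None:
    """Structural invariants every generated scenario must satisfy."""
    for m in scen.truth_models:
        m.validate(scen.genome)
        mrna, prot = spliced_cds(m, scen.genome)
        if not prot.endswith("*") or "*" in prot[:-1]:
            raise _BuildFailure(f"truth model {m.gene_id} CDS not clean")
    # the scenario's truth proteins must concatenate to the evidence protein
    truth_prots = [
        spliced_cds(m, scen.genome)[1].rstrip("*") for m in scen.truth_models
    ]
    if "".join(truth_prots) != scen.protein.sequence:
        raise _BuildFailure(f"truth protein mismatch in scenario {scen.name}")
    for m in scen.corrupted_models:
        m.validate(scen.genome)


def generate_scenario(scenario_class: str, seed: int, max_attempts: int = 60) -> Scenario:
    """Build one scenario, retrying the random draw until the evidence
    guarantees (junction peptides exist, structures recoverable) hold."""
    if scenario_class not in _BUILDERS:
        raise ValueError(f"unknown scenario class {scenario_class!r}")
    last = None
    for attempt in range(max_attempts):
        sub_seed = (seed * 1_000_003 + 7919 * attempt + ord(scenario_class)) % (2**31)
        try:
            scen = _BUILDERS[scenario_class](sub_seed)
            _verify_scenario(scen)
            return scen
        except _BuildFailure as exc:
            last = exc
    raise RuntimeError(
        f"could not generate scenario {scenario_class} after {max_attempts} "
        f"attempts: {last}"
    )


@dataclass
class ScenarioBundle:
    """A complete synthetic study: genome, truth, corrupted annotation,
    evidence, and a manifest of the injected anomalies."""

    genome: dict[str, str]
    truth_models: list[GeneModel]
    corrupted_models: list[GeneModel]
    truth_proteins: list[SeqRecord]
    transcripts: list[SeqRecord]
    peptides: list[PeptideRecord]
    manifest: list[dict]
    seed: int

    def genome_records(self) -> list[SeqRecord]:
        return [SeqRecord(cid, seq) for cid, seq in self.genome.items()]


def _required_unique(scen_list: list[Scenario]) -> bool:
    """Required evidence must map unambiguously bundle-wide.

    Gap segments and genomically-findable peptides must occur exactly once
    in six-frame protein space; junction peptides (which span introns and
    are absent from six-frame space by construction) must occur exactly
    once across the truth proteins.
    """
    orfs = []
    for scen in scen_list:
        for cid, seq in scen.genome.items():
            orfs.extend(six_frame_scan(seq, 7, cid))
    haystacks = [o.protein.replace("L", "I") for o in orfs]
    truth_prots = [
        s.protein.sequence.replace("L", "I") for s in scen_list
    ]

    def count_in(seg: str, hay: list[str]) -> int:
        seg = seg.replace("L", "I")
        total = 0
        for h in hay:
            p = h.find(seg)
            while p >= 0:
                total += 1
                p = h.find(seg, p + 1)
        return total

    for scen in scen_list:
        for seg in scen.gap_segments + scen.genomic_peptides:
            if count_in(seg, haystacks) != 1:
                return False
        for pep in scen.required_peptides:
            if pep in scen.genomic_peptides:
                continue
            if count_in(pep, truth_prots) != 1 or count_in(pep, haystacks) > 0:
                return False
    return True


def generate_bundle(
    seed: int = 42,
    classes: str = SCENARIO_CLASSES,
    decoy_rate: float = 0.0,
    max_attempts: int = 20,
) -> ScenarioBundle:
    """The default synthetic study: one scenario per anomaly class.

    Deterministic given the seed.  Bundle-level verification re-draws
    scenarios until required evidence is unique across the whole genome.
    ``decoy_rate`` adds that fraction of random peptides guaranteed absent
    from both the proteome and the six-frame genome (mapping negatives).
    """
    for round_ in range(max_attempts):
        scen_list = [
            generate_scenario(c, seed + 101 * round_) for c in classes
        ]
        if _required_unique(scen_list):
            break
    else:
        raise RuntimeError("could not assemble a bundle with unique evidence")

    genome: dict[str, str] = {}
    truth, corrupted, proteins, transcripts = [], [], [], []
    peptides: list[PeptideRecord] = []
    seen_peps: set[str] = set()
    manifest = []
    for scen in scen_list:
        genome.update(scen.genome)
        truth.extend(scen.truth_models)
        corrupted.extend(scen.corrupted_models)
        proteins.append(scen.protein)
        transcripts.extend(scen.transcripts)
        for p in scen.peptides:
            if p.sequence not in seen_peps:
                seen_peps.add(p.sequence)
                peptides.append(p)
        manifest.append(
            {
                "scenario": scen.name,
                "target_protein": scen.protein.id,
                "gene_ids": [m.gene_id for m in scen.corrupted_models],
                "expected_records": [
                    {"class": cls, "input_gene_ids": sorted(ids)}
                    for cls, ids in scen.expected_records
                ],
                "required_peptides": list(scen.required_peptides),
                "transcript_ids": [t.id for t in scen.transcripts],
                "expected_anomalies": scen.expected_anomalies,
            }
        )
    if decoy_rate > 0:
        rng = random.Random(seed ^ 0x5EED)
        n_decoys = max(1, round(decoy_rate * len(peptides)))
        haystack = " ".join(
            [s.protein.sequence for s in scen_list]
            + [
                o.protein
                for cid, seq in genome.items()
                for o in six_frame_scan(seq, 7, cid)
            ]
        ).replace("L", "I")
        decoys = []
        while len(decoys) < n_decoys:
            cand = "".join(rng.choice("ACDEFGHINQSTVWY") for _ in range(12))
            if cand.replace("L", "I") not in haystack and cand not in seen_peps:
                decoys.append(cand)
                seen_peps.add(cand)
        peptides.extend(
            PeptideRecord(d, rng.randint(1, 5), "decoy") for d in decoys
        )
        manifest.append(
            {"scenario": "decoys", "gene_ids": [], "expected_records": [],
             "required_peptides": [], "transcript_ids": [],
             "expected_anomalies": {}, "decoy_peptides": decoys}
        )
    return ScenarioBundle(
        genome=genome,
        truth_models=truth,
        corrupted_models=corrupted,
        truth_proteins=proteins,
        transcripts=transcripts,
        peptides=peptides,
        manifest=manifest,
        seed=seed,
    )
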