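"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
All *internal* intervals are 0-based, half-open ``[start, end)``.  GFF3 is
1-based inclusive and BED is 0-based half-open; conversion happens only in
the functions of this module, never downstream.

Gene models may be *patched* across contigs (a real gene split by an
assembly gap) or across strands (a gene interrupted by an inverted assembly
block).  Both are represented by per-exon ``contig``/``strand`` fields; the
GFF3 serialization keeps such models together under one gene ID using
``part=`` and ``order=`` attributes on the feature lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ParseError",
    "SeqRecord",
    "Exon",
    "GeneModel",
    "PeptideRecord",
    "parse_fasta",
    "write_fasta",
    "parse_gff3",
    "write_gff3",
    "parse_peptides",
    "write_peptides",
    "write_bed",
]

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (DNA contig, protein, or transcript)."""

    id: str
    sequence: str
    description: str = ""

    def validate(self, kind: str) -> "SeqRecord":
        if not self.sequence:
            raise ParseError(f"empty sequence for record '{self.id}'")
        alphabet = DNA_ALPHABET if kind == "dna" else PROTEIN_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise ParseError(
                f"record '{self.id}': invalid {kind} characters {sorted(bad)}"
            )
        return self

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Exon:
    """A genomic coding block, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad exon interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Exon") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """An ordered exon chain in 5'->3' transcription order.

    ``has_start``/``has_stop`` record whether the spliced CDS is believed to
    begin with ATG and end with a stop codon; integrity checking against the
    genome is the job of :mod:`proteorefine.anomaly_detection`.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[Exon]
    has_start: bool = True
    has_stop: bool = True
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def cross_contig(self) -> bool:
        return any(e.contig != self.contig for e in self.exons)

    @property
    def mixed_strand(self) -> bool:
        return any(e.strand != self.strand for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def span(self, contig: str | None = None) -> tuple[int, int]:
        """Genomic [start, end) of the exons on ``contig`` (default: primary)."""
        contig = contig or self.contig
        coords = [e for e in self.exons if e.contig == contig]
        if not coords:
            raise ValueError(f"model {self.gene_id} has no exon on {contig}")
        return min(e.start for e in coords), max(e.end for e in coords)

    def contigs(self) -> list[str]:
        seen: list[str] = []
        for e in self.exons:
            if e.contig not in seen:
                seen.append(e.contig)
        return seen

    def validate(self, genome: dict[str, str] | None = None) -> None:
        if not self.exons:
            raise ValueError(f"model {self.gene_id} has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.overlaps(b):
                raise ValueError(f"model {self.gene_id}: overlapping exons")
        if not self.cross_contig and not self.mixed_strand:
            ordered = [e.start for e in self.exons]
            expect = sorted(ordered, reverse=self.strand == "-")
            if ordered != expect:
                raise ValueError(
                    f"model {self.gene_id}: exon order inconsistent with strand"
                )
        if genome is not None:
            for e in self.exons:
                if e.contig not in genome:
                    raise ValueError(f"unknown contig {e.contig}")
                if e.end > len(genome[e.contig]):
                    raise ValueError(
                        f"model {self.gene_id}: exon [{e.start},{e.end}) exceeds "
                        f"contig {e.contig} length {len(genome[e.contig])}"
                    )

    def flipped(self) -> "GeneModel":
        """The same exons read on the opposite strand (reversed order)."""
        flip = "+" if self.strand == "-" else "-"
        exons = [
            replace(e, strand="+" if e.strand == "-" else "-")
            for e in reversed(self.exons)
        ]
        return GeneModel(
            gene_id=self.gene_id,
            contig=self.contig,
            strand=flip,
            exons=exons,
            has_start=False,
            has_stop=False,
            attributes=dict(self.attributes),
        )


@dataclass(frozen=True)
class PeptideRecord:
    """An MS/MS-identified peptide with its spectral-count support."""

    sequence: str
    psm_count: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 5:
            raise ValueError(f"peptide '{self.sequence}' shorter than 5 residues")
        bad = set(self.sequence) - (PROTEIN_ALPHABET - {"*", "X"})
        if bad:
            raise ValueError(
                f"peptide '{self.sequence}': invalid residue "
                f"'{sorted(bad)[0]}'"
            )
        if self.psm_count < 0:
            raise ValueError("psm_count must be non-negative")


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(path, kind: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, order preserved.

    ``kind`` may be ``"dna"`` or ``"protein"`` to enforce the alphabet.
    Empty sequences are rejected with the offending line number.
    """
    # Light structural pre-scan so errors can name a line number; Biopython
    # is tolerant of empty records, which we must reject.
    header_line = None
    n_seq_chars = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith(">"):
                if header_line is not None and n_seq_chars == 0:
                    raise ParseError(
                        f"{path}: empty sequence for header at line {header_line}"
                    )
                header_line = lineno
                n_seq_chars = 0
            elif line:
                if header_line is None:
                    raise ParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                n_seq_chars += len(line)
        if header_line is not None and n_seq_chars == 0:
            raise ParseError(
                f"{path}: empty sequence for header at line {header_line}"
            )

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out = SeqRecord(
            id=rec.id, sequence=str(rec.seq).upper(), description=rec.description
        )
        if kind is not None:
            out.validate(kind)
        records.append(out)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description if rec.description.startswith(rec.id) else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_RESERVED_ATTRS = {"ID", "Parent", "order", "part", "has_start", "has_stop"}


def _fmt_attrs(pairs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs.items())


def write_gff3(models, path) -> None:
    """Serialize gene models to GFF3 (1-based inclusive coordinates).

    Cross-contig or mixed-strand models are written as one gene ID with one
    mRNA part per contig (``part=i/n``) and explicit ``order=`` indices on
    the CDS lines so transcription order survives the round trip.
    """
    lines = ["##gff-version 3"]
    for m in models:
        parts = m.contigs()
        multi = len(parts) > 1 or m.mixed_strand
        extra = {
            k: str(v) for k, v in m.attributes.items() if k not in _RESERVED_ATTRS
        }
        for pi, contig in enumerate(parts, start=1):
            part_exons = [e for e in m.exons if e.contig == contig]
            lo = min(e.start for e in part_exons) + 1
            hi = max(e.end for e in part_exons)
            strand = part_exons[0].strand if multi else m.strand
            gene_attrs = {"ID": f"gene:{m.gene_id}"}
            mrna_attrs = {
                "ID": f"mRNA:{m.gene_id}",
                "Parent": f"gene:{m.gene_id}",
                "has_start": str(m.has_start).lower(),
                "has_stop": str(m.has_stop).lower(),
            }
            if multi:
                gene_attrs["part"] = mrna_attrs["part"] = f"{pi}/{len(parts)}"
            mrna_attrs.update(extra)
            lines.append(
                "\t".join(
                    [contig, "proteorefine", "gene", str(lo), str(hi), ".",
                     strand, ".", _fmt_attrs(gene_attrs)]
                )
            )
            lines.append(
                "\t".join(
                    [contig, "proteorefine", "mRNA", str(lo), str(hi), ".",
                     strand, ".", _fmt_attrs(mrna_attrs)]
                )
            )
        for order, e in enumerate(m.exons):
            attrs = {"ID": f"CDS:{m.gene_id}.{order}", "Parent": f"mRNA:{m.gene_id}"}
            if multi:
                attrs["order"] = str(order)
            lines.append(
                "\t".join(
                    [e.contig, "proteorefine", "CDS", str(e.start + 1),
                     str(e.end), ".", e.strand, "0", _fmt_attrs(attrs)]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _bool_attr(feat, key: str, default: bool = True) -> bool:
    vals = feat.attributes.get(key)
    if not vals:
        return default
    return vals[0].lower() == "true"


def parse_gff3(path, allow_mixed_strand: bool = False) -> list[GeneModel]:
    """Read gene models from GFF3 (one :class:`GeneModel` per mRNA).

    Minus-strand exon lists are returned in transcription order (index 0 is
    the 5' exon).  CDS features are preferred over exon features when both
    are present.  Mixed strands within one mRNA are an error unless
    ``allow_mixed_strand`` is set (such a model is itself evidence of an
    inverted-assembly anomaly and callers may choose to keep it).
    """
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []  # valid but empty (version pragma only)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )

    # Orphan coding features are a structural error.
    for ftype in ("CDS", "exon"):
        for feat in db.features_of_type(ftype):
            if "Parent" not in feat.attributes:
                raise ParseError(
                    f"{path}: {ftype} feature '{feat.id}' has no Parent"
                )

    models = []
    for mrna in db.features_of_type("mRNA"):
        cds = list(db.children(mrna, featuretype="CDS"))
        feats = cds if cds else list(db.children(mrna, featuretype="exon"))
        if not feats:
            if "part" in mrna.attributes:
                # continuation line of a multi-part (cross-contig) mRNA; its
                # CDS children are attached to the primary part
                continue
            raise ParseError(f"{path}: mRNA '{mrna.id}' has no CDS/exon children")
        strands = {f.strand for f in feats}
        mrna_strand = mrna.strand
        if len(strands) > 1 and not allow_mixed_strand:
            ids = ",".join(f.id for f in feats)
            raise ParseError(
                f"{path}: mixed strands within mRNA '{mrna.id}' "
                f"(features {ids}); possible inverted-assembly anomaly"
            )
        exons = [
            (f, Exon(contig=f.seqid, start=f.start - 1, end=f.end, strand=f.strand))
            for f in feats
        ]
        if any("order" in f.attributes for f, _ in exons):
            exons.sort(key=lambda fe: int(fe[0].attributes["order"][0]))
        else:
            exons.sort(key=lambda fe: fe[1].start, reverse=mrna_strand == "-")
        gene_id = mrna.id.split(":", 1)[-1].split("_part")[0]
        parents = mrna.attributes.get("Parent")
        contig = mrna.seqid
        attributes = {
            k: ",".join(v)
            for k, v in mrna.attributes.items()
            if k not in _RESERVED_ATTRS
        }
        model = GeneModel(
            gene_id=gene_id,
            contig=contig,
            strand=mrna_strand,
            exons=[e for _, e in exons],
            has_start=_bool_attr(mrna, "has_start"),
            has_stop=_bool_attr(mrna, "has_stop"),
            attributes=attributes,
        )
        models.append(model)

    # Multi-part mRNAs (cross-contig patches) arrive as one record per part
    # sharing the gene ID; fold them together, 5' part first.
    merged: dict[str, GeneModel] = {}
    ordered_ids: list[str] = []
    for m in models:
        if m.gene_id not in merged:
            merged[m.gene_id] = m
            ordered_ids.append(m.gene_id)
        else:
            first = merged[m.gene_id]
            seen = {(e.contig, e.start, e.end) for e in first.exons}
            extra = [e for e in m.exons if (e.contig, e.start, e.end) not in seen]
            first.exons.extend(extra)
    out = [merged[g] for g in ordered_ids]
    for m in out:
        m.validate()
    return out


# ---------------------------------------------------------------------------
# Peptide TSV


def parse_peptides(path) -> list[PeptideRecord]:
    """Read the peptide evidence table (TSV: peptide, psm_count, source).

    Duplicate peptide sequences are aggregated by summing ``psm_count``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "source": str})
    required = {"peptide", "psm_count", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    valid = PROTEIN_ALPHABET - {"*", "X"}
    records: dict[str, PeptideRecord] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        pep = str(row["peptide"]).strip().upper()
        bad = set(pep) - valid
        if bad:
            raise ParseError(
                f"{path} row {idx + 2}: invalid residue '{sorted(bad)[0]}' "
                f"in peptide '{pep}'"
            )
        count = int(row["psm_count"])
        source = str(row["source"])
        if pep in records:
            prev = records[pep]
            sources = prev.source.split(";")
            if source not in sources:
                sources.append(source)
            records[pep] = PeptideRecord(
                sequence=pep,
                psm_count=prev.psm_count + count,
                source=";".join(sources),
            )
        else:
            records[pep] = PeptideRecord(sequence=pep, psm_count=count, source=source)
            order.append(pep)
    return [records[p] for p in order]


def write_peptides(peptides, path) -> None:
    df = pd.DataFrame(
        {
            "peptide": [p.sequence for p in peptides],
            "psm_count": [p.psm_count for p in peptides],
            "source": [p.source for p in peptides],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals, path) -> None:
    """Write extended BED6 lines (0-based half-open).

    ``intervals`` yields tuples ``(contig, start, end, name, score, strand)``
    optionally followed by extra columns (e.g. a hit category).
    """
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
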