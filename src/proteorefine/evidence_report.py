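"""Expression-evidence tiers and refinement bookkeeping.

After refinement every final gene is assigned a tier -- ``protein`` when at
least one unambiguous MS peptide maps to it, ``transcript_only`` when only
transcript evidence supports it, ``none`` otherwise -- and the ledger is
summarized into the counts a curation study reports: genes before and
after, corrections applied, tier sizes, putative fragments.

The module also ships a worked-example fixture: the curated catalogue of
the *Rhodnius prolixus* A1 aspartic-protease family (gene groups, merge
structure, evidence classes), so the bookkeeping can be exercised without
any download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .io_formats import GeneModel, PeptideRecord, SeqRecord
from .model_refinement import CorrectionRecord, RefinementResult
from .peptide_mapping import map_to_annotated
from .seqcore import spliced_cds, translate

__all__ = [
    "GeneEvidence",
    "LedgerSummary",
    "assign_evidence_tier",
    "build_evidences",
    "summarize",
    "load_table1_fixture",
    "summarize_table1",
]

TIERS = ("protein", "transcript_only", "none")


@dataclass(frozen=True)
class GeneEvidence:
    gene_id: str
    tier: str
    n_unique_peptides: int = 0
    transcript_ids: tuple[str, ...] = ()
    status: str = "gene"  # gene | putative_fragment

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "protein" and self.n_unique_peptides < 1:
            raise ValueError("protein tier requires >= 1 unique peptide")
        if self.tier == "transcript_only" and (
            self.n_unique_peptides != 0 or not self.transcript_ids
        ):
            raise ValueError(
                "transcript_only tier requires transcripts and no peptides"
            )


@dataclass(frozen=True)
class LedgerSummary:
    n_genes_before: int
    n_genes_after: int
    n_corrections: int
    n_protein_tier: int
    n_transcript_only_tier: int
    n_no_evidence: int
    n_putative_fragments: int

    def __post_init__(self) -> None:
        total = self.n_protein_tier + self.n_transcript_only_tier + self.n_no_evidence
        if total != self.n_genes_after:
            raise ValueError(
                f"tier counts ({total}) do not sum to final gene count "
                f"({self.n_genes_after})"
            )


def assign_evidence_tier(
    gene: GeneModel,
    hits_by_gene: dict[str, int],
    transcript_ids: tuple[str, ...],
) -> GeneEvidence:
    """Tier a gene: protein beats transcript_only beats none."""
    n_pep = hits_by_gene.get(gene.gene_id, 0)
    status = gene.attributes.get("status", "gene")
    if n_pep >= 1:
        tier = "protein"
    elif transcript_ids:
        tier = "transcript_only"
    else:
        tier = "none"
    return GeneEvidence(
        gene_id=gene.gene_id,
        tier=tier,
        n_unique_peptides=n_pep,
        transcript_ids=transcript_ids,
        status=status,
    )


def build_evidences(
    result: RefinementResult,
    peptides: list[PeptideRecord],
    transcripts: list[SeqRecord],
    il_equivalent: bool = True,
) -> list[GeneEvidence]:
    """Re-map all evidence onto the final models and tier each gene.

    Intron-retention proteoform models are folded into their parent gene.
    Peptides placing at more than one final locus are discarded as
    ambiguous before counting.
    """
    parents = {}
    for m in result.models:
        parent = m.attributes.get("proteoform_of", m.gene_id)
        parents[m.gene_id] = parent
    genes = [m for m in result.models if m.attributes.get("proteoform_of") is None]

    per_pep_genes: dict[str, set[str]] = {}
    for pep in peptides:
        hit_genes = set()
        for h in map_to_annotated(pep, result.models, result.genome, il_equivalent):
            hit_genes.add(parents[h.gene_id])
        per_pep_genes[pep.sequence] = hit_genes
    counts: dict[str, int] = {}
    for pep, gids in per_pep_genes.items():
        if len(gids) == 1:  # unique evidence only
            g = gids.pop()
            counts[g] = counts.get(g, 0) + 1

    tx_by_gene: dict[str, tuple[str, ...]] = {}
    for m in genes:
        _, prot = spliced_cds(m, result.genome)
        prot = prot.rstrip("*")
        linked = tuple(
            t.id for t in transcripts if translate(t.sequence).rstrip("*") == prot
        )
        tx_by_gene[m.gene_id] = linked

    return [
        assign_evidence_tier(m, counts, tx_by_gene.get(m.gene_id, ()))
        for m in genes
    ]


def _corrected_gene_count(
    records: list[CorrectionRecord], evidences: list[GeneEvidence]
) -> int:
    """Distinct final genes touched by a correction, excluding the
    intron-retention characterization (a proteoform call, not an
    annotation repair)."""
    gene_ids = {e.gene_id for e in evidences}
    affected = set()
    for r in records:
        if r.cls == "intron_retention":
            continue
        if r.output_gene_id and r.output_gene_id in gene_ids:
            affected.add(r.output_gene_id)
            continue
        # genome-level records (inversion fixes) attach to the final gene
        # that absorbed their input models
        for gid in gene_ids:
            if any(src in gid.split("-") for src in r.input_gene_ids):
                affected.add(gid)
                break
    return len(affected)


def summarize(
    records: list[CorrectionRecord],
    evidences: list[GeneEvidence],
    before_models: list[GeneModel],
) -> LedgerSummary:
    """Deterministic bookkeeping; invariant-checked, order-invariant."""
    n_before = len(
        {
            m.gene_id
            for m in before_models
            if m.attributes.get("proteoform_of") is None
        }
    )
    final_genes = [e for e in evidences if e.status == "gene"]
    n_putative = sum(1 for e in evidences if e.status == "putative_fragment")
    tiers = {t: sum(1 for e in final_genes if e.tier == t) for t in TIERS}
    return LedgerSummary(
        n_genes_before=n_before,
        n_genes_after=len(final_genes),
        n_corrections=_corrected_gene_count(records, evidences),
        n_protein_tier=tiers["protein"],
        n_transcript_only_tier=tiers["transcript_only"],
        n_no_evidence=tiers["none"],
        n_putative_fragments=n_putative,
    )


# ---------------------------------------------------------------------------
# Worked-example fixture


def load_table1_fixture() -> dict:
    """The packaged A1 protease-family catalogue (see module docstring)."""
    with resources.files("proteorefine.data").joinpath("table1.json").open() as fh:
        return json.load(fh)


def summarize_table1(fixture: dict | None = None) -> LedgerSummary:
    """Recompute the family bookkeeping from the packaged catalogue.

    All counts are derived from the per-entity data: input gene IDs, merge
    groups, putative-fragment flags, evidence classes and correction
    classes -- nothing is stored pre-aggregated.
    """
    fixture = fixture or load_table1_fixture()
    entities = fixture["entities"]
    n_before = len({g for e in entities for g in e["input_gene_ids"]})
    final_genes = [e for e in entities if e["status"] == "gene"]
    n_putative = sum(1 for e in entities if e["status"] == "putative_fragment")
    n_corr = sum(
        1
        for e in entities
        if e["correction_class"] not in (None, "intron_retention")
    )
    tier_map = {"protein": 0, "transcript": 0, "none": 0}
    for e in final_genes:
        tier_map[e["evidence"]] += 1
    return LedgerSummary(
        n_genes_before=n_before,
        n_genes_after=len(final_genes),
        n_corrections=n_corr,
        n_protein_tier=tier_map["protein"],
        n_transcript_only_tier=tier_map["transcript"],
        n_no_evidence=tier_map["none"],
        n_putative_fragments=n_putative,
    )
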