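import random

import pytest

from _oracles import oracle_peptide_placements
from proteorefine.config import Config
from proteorefine.io_formats import Exon, GeneModel, PeptideRecord
from proteorefine.peptide_mapping import (
    AnnotationIndex,
    classify_all,
    map_to_annotated,
    map_to_genome,
)
from proteorefine.seqcore import revcomp, spliced_cds, translate

CODON = {
    "W": "TGG", "D": "GAT", "N": "AAT", "Q": "CAA", "H": "CAT", "T": "ACT",
    "S": "AGT", "V": "GTT", "E": "GAA", "A": "GCT", "M": "ATG", "K": "AAA",
    "G": "GGT", "I": "ATT", "L": "CTG",
}


def encode(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


def two_exon_gene(protein_a: str, protein_b: str, intron: str = None):
    """A plus-strand two-exon toy gene; exon 1 encodes protein_a."""
    rng = random.Random(11)
    intron = intron or ("GT" + "".join(rng.choice("ACGT") for _ in range(58)) + "AG")
    e1, e2 = encode(protein_a), encode(protein_b) + "TAA"
    pad5 = "".join(rng.choice("ACGT") for _ in range(50))
    pad3 = "".join(rng.choice("ACGT") for _ in range(50))
    contig = pad5 + e1 + intron + e2 + pad3
    s1 = len(pad5)
    model = GeneModel(
        "g1", "c", "+",
        [
            Exon("c", s1, s1 + len(e1), "+"),
            Exon("c", s1 + len(e1) + len(intron), s1 + len(e1) + len(intron) + len(e2), "+"),
        ],
    )
    return {"c": contig}, model


class TestAnnotatedMapping:
    def test_exonic_single_block(self):
        genome, model = two_exon_gene("MADEGHTSV", "WDNQHKTSVE")
        (hit,) = map_to_annotated(PeptideRecord("MADEG"), [model], genome)
        assert hit.category == "exonic"
        assert len(hit.blocks) == 1 and len(hit.blocks[0]) == 15

    def test_junction_block_arithmetic(self):
        genome, model = two_exon_gene("MADEGHTSV", "WDNQHKTSVE")
        # last 2 codons of exon 1 + first 2 of exon 2 -> 2 blocks of 6 nt
        pep = PeptideRecord("SVWDN")
        (hit,) = map_to_annotated(pep, [model], genome)
        assert hit.category == "junction"
        assert [len(b) for b in hit.blocks] == [6, 9]
        assert sum(len(b) for b in hit.blocks) == 3 * len(pep.sequence)
        # translating the concatenated blocks reproduces the peptide
        joined = "".join(genome["c"][b.start : b.end] for b in hit.blocks)
        assert translate(joined) == pep.sequence

    def test_il_equivalence_toggle(self):
        genome, model = two_exon_gene("MADEGHTSI", "WDNQHKTSVE")
        pep = PeptideRecord("GHTSL")  # L vs encoded I
        assert map_to_annotated(pep, [model], genome, il_equivalent=True)
        assert not map_to_annotated(pep, [model], genome, il_equivalent=False)

    def test_minus_strand_blocks(self):
        genome, model = two_exon_gene("MADEGHTSV", "WDNQHKTSVE")
        flipped_genome = {"c": revcomp(genome["c"])}
        L = len(genome["c"])
        exons = [
            Exon("c", L - e.end, L - e.start, "-") for e in model.exons
        ]
        m2 = GeneModel("g1", "c", "-", exons)
        assert spliced_cds(m2, flipped_genome) == spliced_cds(model, genome)
        (hit,) = map_to_annotated(PeptideRecord("SVWDN"), [m2], flipped_genome)
        assert hit.category == "junction"
        assert all(b.strand == "-" for b in hit.blocks)


class TestGenomeMapping:
    def test_novel_intergenic_hit(self):
        genome, model = two_exon_gene("MADEGHTSV", "WDNQHKTSVE")
        planted = encode("WWDDNNQQHH")
        genome = {"c": genome["c"] + "AAA" + planted + "CC"}
        idx = AnnotationIndex.build([model])
        hits = map_to_genome(PeptideRecord("WWDDNNQQHH"), genome, idx)
        assert [h.category for h in hits] == ["novel_region"]
        b = hits[0].blocks[0]
        assert genome["c"][b.start : b.end] == planted

    def test_multi_locus_downgraded_to_ambiguous(self):
        genome, model = two_exon_gene("MADEGHTSV", "WDNQHKTSVE")
        planted = encode("WWDDNNQQHH")
        genome = {"c": genome["c"] + "AAA" + planted + "CCC" + planted}
        idx = AnnotationIndex.build([model])
        hits = map_to_genome(PeptideRecord("WWDDNNQQHH"), genome, idx)
        assert len(hits) == 2
        assert {h.category for h in hits} == {"ambiguous"}

    def test_intronic_hit_flagged_intron_retained(self):
        # plant peptide codons (stop-free, in any frame) inside the intron
        planted = encode("WWDDNNQQHH")
        intron = "GT" + "AT" + planted + "CAT" + "AG"
        genome, model = two_exon_gene("MADEGHTSV", "WDNQHKTSVE", intron=intron)
        idx = AnnotationIndex.build([model])
        hits = map_to_genome(PeptideRecord("WWDDNNQQHH"), genome, idx)
        assert [h.category for h in hits] == ["intron_retained"]
        assert hits[0].gene_id == "g1"

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(3000))
        idx = AnnotationIndex.build([])
        # sample peptides from actual translations so hits exist
        frames = [translate(seq, k) for k in range(3)] + [
            translate(revcomp(seq), k) for k in range(3)
        ]
        peps = set()
        for fr in frames:
            for stretch in fr.split("*"):
                if len(stretch) >= 12:
                    peps.add(stretch[2:11])
        for pep in sorted(peps)[:10]:
            hits = map_to_genome(PeptideRecord(pep), {"c": seq}, idx,
                                 il_equivalent=False)
            mine = {(h.strand, h.blocks[0].start, h.blocks[0].end) for h in hits}
            assert mine == oracle_peptide_placements(seq, pep)


class TestClassifyAll:
    def test_empty_inputs(self):
        assert classify_all([], [], {}) == []

    def test_block_length_invariant_bundle_wide(self, bundle):
        hits = classify_all(
            bundle.peptides, bundle.corrupted_models, bundle.genome, Config()
        )
        for h in hits:
            if h.blocks:
                assert sum(len(b) for b in h.blocks) == 3 * len(h.peptide.sequence)

    def test_truth_models_leave_nothing_unmapped(self, bundle):
        """Peptides digested from truth proteins must all map to truth models."""
        hits = classify_all(
            bundle.peptides, bundle.truth_models, bundle.genome, Config()
        )
        unmapped = [h for h in hits if h.category == "unmapped"]
        # the only peptide absent from the canonical truth proteome is the
        # intron-retention boundary peptide, which maps via the genome search
        assert not unmapped

    def test_zero_hit_peptide_reported_unmapped(self):
        genome, model = two_exon_gene("MADEGHTSV", "WDNQHKTSVE")
        hits = classify_all(
            [PeptideRecord("WWWWWWWW")], [model], genome, Config()
        )
        assert [h.category for h in hits] == ["unmapped"]
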