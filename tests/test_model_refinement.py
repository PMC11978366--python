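import random
from dataclasses import replace

import pytest

from proteorefine.config import Config
from proteorefine.io_formats import Exon, GeneModel, PeptideRecord
from proteorefine.model_refinement import (
    call_intron_retention,
    correct_inversion,
    infer_novel_exon,
    refine_all,
)
from proteorefine.peptide_mapping import PeptideGenomicHit
from proteorefine.seqcore import revcomp, spliced_cds

CODON = {
    "A": "GCT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT", "H": "CAT",
    "K": "AAA", "M": "ATG", "N": "AAT", "Q": "CAA", "S": "TCT", "T": "ACT",
    "V": "GTC", "W": "TGG", "Y": "TAT",
}


def encode(protein):
    return "".join(CODON[a] for a in protein)


def _hit(contig, start, end, strand, pep):
    return PeptideGenomicHit(
        peptide=PeptideRecord(pep),
        contig=contig,
        strand=strand,
        blocks=[Exon(contig, start, end, strand)],
        category="novel_region",
    )


class TestInferNovelExon:
    def _toy(self):
        # intergenic ORF flanked by AG ... GT, peptide inside
        exon_aa = "WDNQHTSVEAGH"  # 12 residues
        exon = encode(exon_aa)
        rng = random.Random(41)
        left = "".join(rng.choice("AC") for _ in range(40)) + "AG"
        right = "GT" + "".join(rng.choice("AC") for _ in range(40))
        contig = left + exon + right
        s = len(left)
        return contig, exon_aa, s, s + len(exon)

    def test_exact_canonical_boundaries(self):
        contig, aa, s, e = self._toy()
        # the peptide covers interior residues 2..10
        hit = _hit("c", s + 6, s + 30, "+", aa[2:10])
        exon = infer_novel_exon([hit], {"c": contig})
        assert (exon.start, exon.end) == (s, e)

    def test_terminal_exon_ends_at_stop(self):
        contig, aa, s, e = self._toy()
        contig = contig[:e] + "TAA" + contig[e + 3 :]
        hit = _hit("c", s + 6, s + 30, "+", aa[2:10])
        exon = infer_novel_exon([hit], {"c": contig}, terminal=True)
        assert (exon.start, exon.end) == (s, e + 3), "stop codon included"

    def test_unreachable_boundaries_unresolved(self):
        contig, aa, s, e = self._toy()
        # destroy the donor downstream: no GT within the window
        contig = contig[:e] + "A" * 40
        hit = _hit("c", s + 6, s + 30, "+", aa[2:10])
        assert infer_novel_exon([hit], {"c": contig}) is None

    def test_conflicting_frames_rejected(self):
        contig, aa, s, e = self._toy()
        h1 = _hit("c", s, s + 24, "+", aa[0:8])
        h2 = _hit("c", s + 7, s + 31, "+", aa[2:10])  # off-grid by 1
        with pytest.raises(ValueError, match="conflicting reading frames"):
            infer_novel_exon([h1, h2], {"c": contig})


class TestCorrectInversion:
    def test_roundtrip_and_remap(self):
        rng = random.Random(51)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        genome = {"c": seq}
        inside = GeneModel("in", "c", "+", [Exon("c", 120, 150, "+")])
        outside = GeneModel("out", "c", "+", [Exon("c", 10, 40, "+")])
        new_genome, new_models, rec = correct_inversion(
            genome, "c", (100, 200), [inside, outside], ("transcript:t",)
        )
        assert rec.cls == "inversion_fix"
        assert new_genome["c"][100:200] == revcomp(seq[100:200])
        moved = next(m for m in new_models if m.gene_id == "in")
        kept = next(m for m in new_models if m.gene_id == "out")
        assert kept.exons == outside.exons
        # an unrelated gene fully inside the block is re-coordinated but its
        # protein is sequence-identical
        assert spliced_cds(moved, new_genome)[0] == spliced_cds(inside, genome)[0]
        assert moved.exons[0].strand == "-"

    def test_straddling_exon_rejected(self):
        genome = {"c": "ACGT" * 100}
        m = GeneModel("g", "c", "+", [Exon("c", 90, 130, "+")])
        with pytest.raises(ValueError, match="straddles"):
            correct_inversion(genome, "c", (100, 200), [m], ("e",))


class TestIntronRetention:
    def _ir_gene(self, retained_aa="VADEQGK", break_after=True):
        """Two-exon gene whose intron 2 starts with an in-frame retained
        segment bounded by an alternative GT donor."""
        exon1_aa = "MDAEG" + "K" + "WDNQHTSVE"  # K gives the tryptic cut
        exon2_aa = "GHTSADEWFK"
        retained = "".join(CODON[a] for a in retained_aa)
        assert retained.startswith("GT")
        tail = "TAA" if break_after else "CAT"
        intron = retained + "GT" + "A" + tail + "ACGTACCA" * 6 + "AG"
        e1 = encode(exon1_aa)
        e2 = encode(exon2_aa) + "TAA"
        contig = "CCAACC" + e1 + intron + e2 + "TTGGTT"
        s1 = 6
        model = GeneModel(
            "g", "c", "+",
            [
                Exon("c", s1, s1 + len(e1), "+"),
                Exon("c", s1 + len(e1) + len(intron),
                     s1 + len(e1) + len(intron) + len(e2), "+"),
            ],
        )
        boundary_pep = "WDNQHTSVE" + retained_aa
        # genomic block of the boundary peptide (contiguous across boundary)
        b_start = s1 + len(e1) - 27
        b_end = s1 + len(e1) + 3 * len(retained_aa)
        hit = PeptideGenomicHit(
            peptide=PeptideRecord(boundary_pep),
            contig="c", strand="+",
            blocks=[Exon("c", b_start, b_end, "+")],
            category="intron_retained", gene_id="g",
        )
        return {"c": contig}, model, hit, retained_aa

    def test_call_produces_proteoform_pair(self):
        genome, model, hit, retained_aa = self._ir_gene()
        pair, retained_model, rec = call_intron_retention(model, [hit], genome)
        assert pair.extra_residues == len(retained_aa)
        assert pair.retained_intron_index == 1
        assert pair.retained == pair.canonical[:15] + retained_aa + pair.canonical[15:]
        # retained model must actually encode the retained proteoform
        _, prot = spliced_cds(retained_model, genome)
        assert prot.rstrip("*") == pair.retained

    def test_refusal_when_retention_hits_stop(self):
        # without a downstream in-frame arrangement the only candidate donor
        # leads through a stop: no call
        genome, model, hit, _ = self._ir_gene(retained_aa="VADEQGK")
        seq = genome["c"]
        # replace the retained segment's 3rd codon with TAA (in-frame stop)
        off = model.exons[0].end + 6
        genome = {"c": seq[:off] + "TAA" + seq[off + 3 :]}
        hit2 = replace(hit)  # same evidence
        assert call_intron_retention(model, [hit2], genome) is None

    def test_no_call_without_junction_crossing(self):
        genome, model, hit, _ = self._ir_gene()
        inside = PeptideGenomicHit(
            peptide=PeptideRecord("WDNQHTSVE"),
            contig="c", strand="+",
            blocks=[Exon("c", model.exons[0].end - 27, model.exons[0].end, "+")],
            category="intron_retained", gene_id="g",
        )
        assert call_intron_retention(model, [inside], genome) is None


class TestRefineAllSuite:
    def test_every_injected_anomaly_corrected(self, bundle, refined):
        expected = sorted(
            (rec["class"], tuple(rec["input_gene_ids"]))
            for entry in bundle.manifest
            for rec in entry["expected_records"]
        )
        observed = sorted(
            (r.cls, tuple(sorted(r.input_gene_ids))) for r in refined.records
        )
        assert observed == expected
        assert refined.unresolved == []

    def test_corrected_proteins_equal_truth(self, bundle, refined):
        truth = {p.id: p.sequence for p in bundle.truth_proteins}
        by_key = {}
        for m in refined.models:
            if m.attributes.get("proteoform_of"):
                continue
            key = tuple(sorted(m.attributes.get("merged_from", m.gene_id).split(",")))
            by_key[key] = m
        for entry in bundle.manifest:
            if not entry["gene_ids"]:
                continue
            key = tuple(sorted(entry["gene_ids"]))
            model = by_key.get(key) or by_key.get((entry["gene_ids"][0],))
            _, prot = spliced_cds(model, refined.genome)
            assert prot.rstrip("*") == truth[entry["target_protein"]], entry["scenario"]

    def test_gene_count_ledger_arithmetic(self, bundle, refined):
        n_in = len({m.gene_id for m in bundle.corrupted_models})
        finals = [
            m for m in refined.models if not m.attributes.get("proteoform_of")
        ]
        merged_away = sum(
            len(m.attributes["merged_from"].split(",")) - 1
            for m in finals
            if "merged_from" in m.attributes
        )
        assert len(finals) == n_in - merged_away

    def test_no_internal_stops_in_output(self, bundle, refined):
        for m in refined.models:
            _, prot = spliced_cds(m, refined.genome)
            assert "*" not in prot.rstrip("*")
            assert prot.endswith("*")

    def test_idempotence(self, bundle, refined):
        second = refine_all(
            refined.genome, refined.models, bundle.peptides,
            bundle.truth_proteins, bundle.transcripts, Config(),
        )
        assert second.records == []
        assert second.unresolved == []

    def test_truth_models_need_no_structural_corrections(self, bundle):
        """True annotation on the as-released genome needs no gene repairs.

        Two records legitimately remain: the genome-level inversion fix
        (the released assembly physically contains the inverted block no
        matter how the models describe it) and the intron-retention
        proteoform characterization (absent from the canonical models).
        """
        res = refine_all(
            bundle.genome, bundle.truth_models, bundle.peptides,
            bundle.truth_proteins, bundle.transcripts, Config(),
        )
        assert sorted(r.cls for r in res.records) == [
            "intron_retention", "inversion_fix",
        ]
        assert res.unresolved == []

    def test_ablation_moves_case_to_unresolved(self, bundle, refined):
        required = {
            p
            for entry in bundle.manifest
            if entry["scenario"] == "A"
            for p in entry["required_peptides"]
        }
        peptides = [p for p in bundle.peptides if p.sequence not in required]
        res = refine_all(
            bundle.genome, bundle.corrupted_models, peptides,
            bundle.truth_proteins, bundle.transcripts, Config(),
        )
        assert [sorted(u.gene_ids) for u in res.unresolved] == [["geneA1", "geneA2"]]
        kept = sorted(
            (r.cls, tuple(sorted(r.input_gene_ids))) for r in res.records
        )
        baseline = sorted(
            (r.cls, tuple(sorted(r.input_gene_ids)))
            for r in refined.records
            if "geneA1" not in r.input_gene_ids
        )
        assert kept == baseline, "no other scenario may change"

    def test_ablation_monotonicity(self, bundle, refined):
        """Removing evidence never creates new corrections."""
        rng = random.Random(71)
        peptides = [p for p in bundle.peptides if rng.random() > 0.3]
        res = refine_all(
            bundle.genome, bundle.corrupted_models, peptides,
            bundle.truth_proteins, bundle.transcripts, Config(),
        )
        base = {(r.cls, tuple(sorted(r.input_gene_ids))) for r in refined.records}
        sub = {(r.cls, tuple(sorted(r.input_gene_ids))) for r in res.records}
        assert sub <= base
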