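import random

import pytest

from _oracles import oracle_glocal_score
from proteorefine.anomaly_detection import (
    align_proteins,
    check_model_integrity,
    detect_fragment_relation,
    detect_inversion,
    spliced_align_transcript,
)
from proteorefine.io_formats import Exon, GeneModel
from proteorefine.seqcore import revcomp

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _rand_protein(rng, n):
    return "".join(rng.choice(AAS) for _ in range(n))


def _rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestIntegrity:
    @pytest.mark.parametrize(
        "cds,expected",
        [
            ("ATGAAATAA", []),
            ("ATGAAAAAA", ["missing_stop"]),
            ("ATGTAAAAATAA", ["internal_stop"]),
            ("AAAAAATAA", ["missing_start"]),
            ("CCCTAACCC", ["missing_start", "internal_stop", "missing_stop"]),
        ],
    )
    def test_check_order_and_classes(self, cds, expected):
        m = GeneModel("g", "c", "+", [Exon("c", 0, len(cds), "+")])
        got = [a.cls for a in check_model_integrity(m, {"c": cds})]
        assert got == expected

    def test_strand_invariance(self):
        cds = "ATGTAAAAAGGG"
        plus = GeneModel("g", "c", "+", [Exon("c", 5, 5 + len(cds), "+")])
        contig = "TTTTT" + cds + "CCCCC"
        flipped = revcomp(contig)
        L = len(contig)
        minus = GeneModel("g", "c", "-", [Exon("c", L - 5 - len(cds), L - 5, "-")])
        a = [x.cls for x in check_model_integrity(plus, {"c": contig})]
        b = [x.cls for x in check_model_integrity(minus, {"c": flipped})]
        assert a == b


class TestAligner:
    def test_identity_self(self):
        r = align_proteins("PEPTIDE", "PEPTIDE")
        assert (r.identity, r.coverage_query, r.coverage_target) == (1.0, 1.0, 1.0)

    def test_fragment_span_and_coverage(self):
        rng = random.Random(5)
        t = _rand_protein(rng, 200)
        q = t[:100]
        r = align_proteins(q, t)
        assert r.identity == 1.0
        assert r.coverage_target == 0.5
        assert r.target_span == (0, 100)

    def test_mismatched_fragment(self):
        rng = random.Random(6)
        t = _rand_protein(rng, 200)
        q = list(t[50:120])
        q[10] = "W" if q[10] != "W" else "Y"
        q[40] = "W" if q[40] != "W" else "Y"
        r = align_proteins("".join(q), t)
        assert r.identity >= 0.97
        assert r.target_span == (50, 120)

    @pytest.mark.parametrize("seed", range(8))
    def test_score_equals_dp_oracle(self, seed):
        rng = random.Random(seed)
        m = rng.randint(20, 160)
        t = _rand_protein(rng, m)
        if seed % 2:
            a = rng.randint(0, m // 2)
            b = rng.randint(a + 8, m)
            q = list(t[a:b])
            for _ in range(rng.randint(0, 3)):
                q[rng.randrange(len(q))] = rng.choice(AAS)
            q = "".join(q)
        else:
            q = _rand_protein(rng, rng.randint(8, m))
        r = align_proteins(q, t)
        assert r.score == oracle_glocal_score(t, q)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("", "PEPTIDE")


class TestFragmentRelation:
    def test_two_halves_one_map(self):
        rng = random.Random(9)
        # build two single-exon genes whose proteins are halves of one target
        codons = {a: c for c, a in
                  [("GCT","A"),("TGT","C"),("GAT","D"),("GAA","E"),("TTT","F"),
                   ("GGT","G"),("CAT","H"),("ATT","I"),("AAA","K"),("CTG","L"),
                   ("ATG","M"),("AAT","N"),("CCT","P"),("CAA","Q"),("CGT","R"),
                   ("AGT","S"),("ACT","T"),("GTT","V"),("TGG","W"),("TAT","Y")]}
        full = "M" + _rand_protein(rng, 119)
        dna1 = "".join(codons[a] for a in full[:60])
        dna2 = "".join(codons[a] for a in full[60:]) + "TAA"
        pad = _rand_dna(rng, 60)
        genome = {"c": pad + dna1 + _rand_dna(rng, 200) + dna2 + pad}
        m1 = GeneModel("f1", "c", "+", [Exon("c", 60, 60 + len(dna1), "+")])
        s2 = 60 + len(dna1) + 200
        m2 = GeneModel("f2", "c", "+", [Exon("c", s2, s2 + len(dna2), "+")])
        maps = detect_fragment_relation([m1, m2], {"T": full}, genome)
        assert len(maps) == 1
        fm = maps[0]
        assert fm.gene_ids() == ["f1", "f2"]
        assert fm.combined_coverage >= 0.95
        assert fm.adjacent_pairs == [("f1", "f2")]

    def test_three_way_split(self, bundle, refined):
        maps = detect_fragment_relation(
            bundle.corrupted_models,
            {p.id: p.sequence for p in bundle.truth_proteins},
            bundle.genome,
        )
        d = next(m for m in maps if m.full_length_id == "protD")
        assert [p.gene_id for p in d.placements] == ["geneD1", "geneD2", "geneD3"]
        spans = [p.target_span for p in d.placements]
        assert all(a[1] <= b[0] + 5 for a, b in zip(spans, spans[1:]))

    def test_wrong_strand_fragment_placed_flipped(self, bundle):
        maps = detect_fragment_relation(
            bundle.corrupted_models,
            {p.id: p.sequence for p in bundle.truth_proteins},
            bundle.genome,
        )
        a = next(m for m in maps if m.full_length_id == "protA")
        flips = {p.gene_id: p.flipped for p in a.placements}
        assert flips == {"geneA1": False, "geneA2": True}

    def test_unrelated_protein_yields_no_map(self):
        rng = random.Random(13)
        genome = {"c": _rand_dna(rng, 400)}
        m = GeneModel("g", "c", "+", [Exon("c", 0, 90, "+")])
        maps = detect_fragment_relation([m], {"T": _rand_protein(rng, 120)}, genome)
        assert maps == []


class TestTranscriptChain:
    def test_two_block_exact_boundaries(self):
        rng = random.Random(21)
        e1, e2 = _rand_dna(rng, 120), _rand_dna(rng, 90)
        intron = "GT" + _rand_dna(rng, 496) + "AG"
        contig = _rand_dna(rng, 300) + e1 + intron + e2 + _rand_dna(rng, 300)
        chain = spliced_align_transcript(e1 + e2, contig, "c")
        assert chain.strand == "+"
        assert [(x.start, x.end) for x in chain.exons] == [
            (300, 420), (920, 1010)
        ]
        assert chain.unplaced == [] and chain.coverage == 1.0

    def test_unplaced_middle_reported(self):
        rng = random.Random(22)
        e1, e2 = _rand_dna(rng, 120), _rand_dna(rng, 90)
        contig = _rand_dna(rng, 200) + e1 + _rand_dna(rng, 400) + e2 + _rand_dna(rng, 200)
        missing = _rand_dna(rng, 150)
        chain = spliced_align_transcript(e1 + missing + e2, contig, "c")
        assert chain.coverage < 1.0
        assert len(chain.unplaced) == 1
        lo, hi = chain.unplaced[0]
        assert lo >= 115 and hi <= 275  # the missing middle, up to greedy slack

    def test_minus_strand_symmetry(self):
        rng = random.Random(23)
        e1, e2 = _rand_dna(rng, 120), _rand_dna(rng, 90)
        intron = "GT" + _rand_dna(rng, 200) + "AG"
        contig = _rand_dna(rng, 150) + e1 + intron + e2 + _rand_dna(rng, 150)
        chain = spliced_align_transcript(e1 + e2, revcomp(contig), "c")
        assert chain.strand == "-"
        assert chain.spliced_sequence({"c": revcomp(contig)}) == e1 + e2

    def test_truth_chains_reproduce_truth_exons(self, bundle):
        # every bundled transcript must chain exactly onto its (corrected)
        # gene structure; exercised here for the upstream-truncation case
        tx = next(t for t in bundle.transcripts if t.id == "txG")
        truth = next(m for m in bundle.truth_models if m.gene_id == "geneG1")
        chain = spliced_align_transcript(
            tx.sequence, bundle.genome[truth.contig], truth.contig
        )
        assert [(e.start, e.end) for e in chain.exons] == [
            (e.start, e.end) for e in truth.exons
        ]

    def test_no_block_long_enough(self):
        assert spliced_align_transcript("ACGT" * 4, "TTTT" * 50, "c").exons == []


class TestInversionDetection:
    def test_middle_block_recovered_exactly(self):
        rng = random.Random(31)
        A, B, C = _rand_dna(rng, 200), _rand_dna(rng, 300), _rand_dna(rng, 200)
        contig = _rand_dna(rng, 100) + A + revcomp(B) + C + _rand_dna(rng, 100)
        anom = detect_inversion(A + B + C, contig, "c")
        assert anom is not None and anom.cls == "inversion"
        assert anom.evidence[0] == ("c", 300, 600)

    def test_consistent_contig_no_anomaly(self):
        rng = random.Random(32)
        A, B = _rand_dna(rng, 200), _rand_dna(rng, 200)
        contig = _rand_dna(rng, 100) + A + B + _rand_dna(rng, 100)
        assert detect_inversion(A + B, contig, "c") is None

    def test_inverted_block_at_contig_edge(self):
        # the un-inverted part must dominate so orientation is unambiguous
        rng = random.Random(33)
        A, B = _rand_dna(rng, 160), _rand_dna(rng, 300)
        contig = revcomp(A) + B + _rand_dna(rng, 100)
        anom = detect_inversion(A + B, contig, "c")
        assert anom is not None
        assert anom.evidence[0] == ("c", 0, 160), "interval abuts position 0"
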