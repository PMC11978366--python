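import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_digest, oracle_six_frame
from proteorefine.io_formats import Exon, GeneModel
from proteorefine.seqcore import (
    find_splice_sites,
    revcomp,
    six_frame_scan,
    spliced_cds,
    translate,
    tryptic_digest,
    tryptic_digest_positions,
)

dna = st.text(alphabet="ACGTN", min_size=0, max_size=200)


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,offset,expected",
        [
            ("ATGGCTTAA", 0, "MA*"),
            ("ATGGCTTAA", 1, "WL"),  # TGG, CTT; trailing AA dropped
            ("ATGNCT", 0, "MX"),
            ("", 0, ""),
            ("AT", 0, ""),
        ],
    )
    def test_examples(self, seq, offset, expected):
        assert translate(seq, offset) == expected

    @given(dna, st.integers(0, 2))
    @settings(max_examples=60, derandomize=True)
    def test_frame_shift_identity(self, seq, k):
        assert translate(seq, k) == translate(seq[k:], 0)

    def test_bad_offset(self):
        with pytest.raises(ValueError):
            translate("ATG", 3)


class TestSplicedCds:
    def test_single_plus_exon(self):
        g = {"c": "ATGAAATAA"}
        m = GeneModel("g", "c", "+", [Exon("c", 0, 9, "+")])
        assert spliced_cds(m, g) == ("ATGAAATAA", "MK*")

    def test_two_minus_exons(self):
        # construct by reverse-complementing each block of ATGAAA|TAA
        block1, block2 = "ATGAAA", "TAA"
        contig = revcomp(block2) + "GGGG" + revcomp(block1)
        g = {"c": contig}
        m = GeneModel(
            "g", "c", "-",
            [Exon("c", 7, 13, "-"), Exon("c", 0, 3, "-")],  # transcription order
        )
        assert spliced_cds(m, g) == ("ATGAAATAA", "MK*")

    def test_out_of_bounds_raises(self):
        m = GeneModel("g", "c", "+", [Exon("c", 0, 12, "+")])
        with pytest.raises(ValueError, match="out of bounds"):
            spliced_cds(m, {"c": "ATGAAA"})

    def test_truth_models_reproduce_truth_proteins(self, bundle):
        by_id = {p.id: p.sequence for p in bundle.truth_proteins}
        by_target: dict[str, list] = {}
        for entry in bundle.manifest:
            if entry["gene_ids"]:
                by_target[entry["target_protein"]] = entry["gene_ids"]
        # scenario truth models concatenate to the scenario protein
        prots = {}
        for m in bundle.truth_models:
            _, p = spliced_cds(m, bundle.genome)
            assert p.endswith("*") and "*" not in p[:-1]
            prots[m.gene_id] = p.rstrip("*")
        joined = "".join(prots.values())
        assert all(seq in joined for seq in by_id.values())


class TestTrypticDigest:
    @pytest.mark.parametrize(
        "protein,mc,expected",
        [
            ("MKRAPK", 0, ["MK", "R", "APK"]),
            ("AKPR", 0, ["AKPR"]),  # K before P is not cleaved
            ("MKRAPK", 1, ["MK", "MKR", "R", "RAPK", "APK"]),
        ],
    )
    def test_examples(self, protein, mc, expected):
        assert tryptic_digest(protein, mc, 1, 50) == expected

    def test_length_filter(self):
        peps = tryptic_digest("MKRAPK", 0, 2, 50)
        assert peps == ["MK", "APK"]

    def test_rejects_stop_characters(self):
        with pytest.raises(ValueError):
            tryptic_digest("MK*AP", 0)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    @settings(max_examples=80, derandomize=True)
    def test_reconstruction_and_oracle(self, protein):
        peps = tryptic_digest(protein, 0, 1, 10_000)
        assert "".join(peps) == protein
        assert peps == oracle_digest(protein)

    def test_positions_are_real_offsets(self):
        protein = "MKRAPKWWWK"
        for s, p in tryptic_digest_positions(protein, 2, 1, 50):
            assert protein[s : s + len(p)] == p


class TestSixFrameScan:
    def test_simple_plus_hit(self):
        hits = six_frame_scan("ATGAAATAA", 2, "c")
        assert any(
            h.strand == "+" and h.frame == 0 and h.protein == "MK" for h in hits
        )

    def test_strand_symmetry(self):
        seq = "ATGAAATAA"
        plus = {(h.strand, h.start, h.end, h.protein) for h in six_frame_scan(seq, 2)}
        minus = {
            ("+" if h.strand == "-" else "-", len(seq) - h.end, len(seq) - h.start,
             h.protein)
            for h in six_frame_scan(revcomp(seq), 2)
        }
        assert plus == minus

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(3000))
        mine = {(h.strand, h.start, h.end, h.protein) for h in six_frame_scan(seq, 8)}
        assert mine == oracle_six_frame(seq, 8)

    def test_span_is_three_times_protein(self, bundle):
        for cid, seq in list(bundle.genome.items())[:3]:
            for h in six_frame_scan(seq, 8, cid):
                assert h.end - h.start == 3 * len(h.protein)


class TestSpliceSites:
    def test_plus_donor(self):
        sites = find_splice_sites("AAGTAA")
        donors = [s for s in sites if s.kind == "donor" and s.strand == "+"]
        assert [d.position for d in donors] == [2]

    def test_plus_acceptor(self):
        sites = find_splice_sites("AAAGAA")
        acc = [s for s in sites if s.kind == "acceptor" and s.strand == "+"]
        assert [a.position for a in acc] == [3]

    def test_no_sites(self):
        assert find_splice_sites("AAAAAA") == []

    def test_minus_strand_orientation(self):
        # plus-strand "AC" is a minus-strand donor GT read right-to-left
        sites = find_splice_sites("AACAA")
        donors = [s for s in sites if s.kind == "donor" and s.strand == "-"]
        assert len(donors) == 1 and donors[0].position == 2

    def test_window_restriction(self):
        seq = "GTAAAAGT"
        all_d = [s for s in find_splice_sites(seq) if s.kind == "donor" and s.strand == "+"]
        windowed = [
            s for s in find_splice_sites(seq, window=(2, 8))
            if s.kind == "donor" and s.strand == "+"
        ]
        assert [s.position for s in all_d] == [0, 6]
        assert [s.position for s in windowed] == [6]
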