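import random

import pytest
from Bio.Seq import Seq

from sscv.consequence import (
    AMBIGUOUS,
    CRYPTIC_EXON,
    EXON_EXTENSION,
    PARTIAL_EXON_LOSS,
    DepthTrack,
    classify,
    classify_consequence,
    hgvs_protein_change,
    locate_affected_exon,
    nmd_susceptibility,
    predict_protein_effect,
    reconstruct_transcript,
    select_reference_transcript,
)
from sscv.models import (
    ACCEPTOR,
    DONOR,
    Genome,
    ReadRecord,
    SpliceJunction,
    SpliceSite,
    TranscriptModel,
)
from sscv.simulate import Scenario, SpliceSimulator
from sscv.discovery import detect_sscvs
from tests.conftest import make_call, make_junction, make_pnj


def tx(tid, exons, strand="+", tags=(), cds=None):
    return TranscriptModel(
        transcript_id=tid, gene_id="G", gene_name="G", chrom="chr1", strand=strand,
        exons=tuple(exons), tags=frozenset(tags),
        cds_start=cds[0] if cds else None, cds_end=cds[1] if cds else None,
    )


class TestReferenceTranscript:
    def test_mane_select_beats_longer(self):
        mane = tx("ENST2", [(900, 1000), (1101, 1200)], tags=["MANE_Select"])
        longer = tx("ENST1", [(800, 1000), (1101, 1300)])
        pick = select_reference_transcript(SpliceSite(1100, ACCEPTOR), "chr1", [longer, mane])
        assert pick.transcript_id == "ENST2"

    def test_mane_plus_clinical_second(self):
        mpc = tx("ENST9", [(900, 1000), (1101, 1200)], tags=["MANE_Plus_Clinical"])
        longer = tx("ENST1", [(800, 1000), (1101, 1300)])
        pick = select_reference_transcript(SpliceSite(1100, ACCEPTOR), "chr1", [longer, mpc])
        assert pick.transcript_id == "ENST9"

    def test_largest_then_earlier_id(self):
        a = tx("ENST00000000002", [(900, 1000), (1101, 1200)])
        b = tx("ENST00000000001", [(900, 1000), (1101, 1200)])
        big = tx("ENST00000000009", [(700, 1000), (1101, 1400)])
        assert select_reference_transcript(SpliceSite(1100, ACCEPTOR), "chr1", [a, b]).transcript_id == "ENST00000000001"
        assert select_reference_transcript(SpliceSite(1100, ACCEPTOR), "chr1", [a, big]).transcript_id == "ENST00000000009"

    def test_no_transcript_matches(self):
        assert select_reference_transcript(SpliceSite(5000, DONOR), "chr1", [tx("T", [(1, 10), (20, 30)])]) is None


class TestAffectedExon:
    def test_donor_novel_in_intron(self):
        t = tx("T", [(900, 1000), (1101, 1200)])
        idx, exon, hijacked = locate_affected_exon(1051, DONOR, t)
        assert (exon, hijacked) == ((900, 1000), 1000)

    def test_donor_novel_inside_exon(self):
        t = tx("T", [(900, 1000), (1101, 1200)])
        idx, exon, hijacked = locate_affected_exon(951, DONOR, t)
        assert exon == (900, 1000)

    def test_acceptor_upstream_of_all_exons(self):
        t = tx("T", [(900, 1000), (1101, 1200)])
        assert locate_affected_exon(1300, ACCEPTOR, t) is None

    def test_minus_strand_mirrored(self):
        t = tx("T", [(900, 1000), (1101, 1200)], strand="-")
        # donor creation on minus strand: affected exon is downstream in
        # genomic coordinates; its genomic start is the hijacked splice site
        idx, exon, hijacked = locate_affected_exon(1051, DONOR, t)
        assert (exon, hijacked) == ((1101, 1200), 1101)


def _depth(chrom="chr1", intervals=()):
    reads = []
    for i, (s, e) in enumerate(intervals):
        n = e - s + 1
        reads.append(ReadRecord(f"d{i}", "A" * n, chrom, ((s, e),)))
    return DepthTrack(reads)


class TestClassify:
    def setup_method(self):
        self.tx = tx("T", [(900, 1000), (1101, 1200), (1501, 1600)], cds=(950, 1550))

    def call(self, novel, side=DONOR, matching=1100):
        m_side = ACCEPTOR if side == DONOR else DONOR
        lo, hi = min(novel, matching), max(novel, matching)
        pnj = make_pnj(make_junction(lo, hi, 9), matching, m_side, novel)
        return make_call(novel - 1, "A", "G", side, -1, pnj)

    def test_partial_exon_loss(self):
        c = classify(self.call(951), self.tx, [], _depth())
        assert c.category == PARTIAL_EXON_LOSS
        assert c.size_change == -50
        assert c.changed_interval == (951, 1000)
        assert c.hijacked_ss == 1000

    def test_exon_extension_needs_full_depth(self):
        covered = _depth(intervals=[(995, 1060)])
        c = classify(self.call(1051), self.tx, [], covered)
        assert c.category == EXON_EXTENSION
        assert c.size_change == 50
        gap = _depth(intervals=[(995, 1020), (1030, 1060)])
        c2 = classify(self.call(1051), self.tx, [], gap)
        assert c2.category == AMBIGUOUS

    def test_cryptic_exon_with_secondary_junction(self):
        novel = 1085  # deep in the intron
        secondary = 1020  # acceptor of the junction from the hijacked donor
        junctions = [SpliceJunction("chr1", 1001, secondary, "+", 4)]
        c = classify(self.call(novel), self.tx, junctions, _depth())
        assert c.category == CRYPTIC_EXON
        assert c.secondary_ss == secondary
        assert c.changed_interval == (1021, 1084)
        assert c.size_change == 64

    def test_cryptic_window_limit(self):
        t = tx("T", [(900, 1000), (2101, 2200)], cds=(950, 2150))
        novel = 1400
        far = SpliceJunction("chr1", 1001, 1050, "+", 4)  # 350 bp from novel SS
        pnj = make_pnj(make_junction(1400, 2100, 9), 2100, ACCEPTOR, 1400)
        call = make_call(1399, "A", "G", DONOR, -1, pnj)
        c = classify(call, t, [far], _depth())
        assert c.category != CRYPTIC_EXON
        near = SpliceJunction("chr1", 1001, 1150, "+", 4)  # 250 bp away
        c2 = classify(call, t, [near], _depth())
        assert c2.category == CRYPTIC_EXON

    def test_most_supported_secondary_wins(self):
        junctions = [
            SpliceJunction("chr1", 1001, 1020, "+", 2),
            SpliceJunction("chr1", 1001, 1040, "+", 9),
        ]
        c = classify(self.call(1085), self.tx, junctions, _depth())
        assert c.secondary_ss == 1040


class TestProteinPrediction:
    def test_inframe_extension_no_stop(self):
        ref_cds = "ATG" + "GCT" * 10 + "TAA"
        insert = "GCA" * 43  # 129 bp, stop-free
        alt_cds = "ATG" + "GCT" * 5 + insert + "GCT" * 5 + "TAA"
        frame, ptc, (ra, aa) = predict_protein_effect(ref_cds, alt_cds, 129)
        assert (frame, ptc) == ("in_frame", "non_ptc")
        assert len(aa) - len(ra) == 43

    def test_frameshift_from_50bp_loss(self):
        ref_cds = "ATG" + "GCT" * 40 + "TAA"
        alt_cds = ref_cds[:30] + ref_cds[80:]
        frame, ptc, _ = predict_protein_effect(ref_cds, alt_cds, -50)
        assert frame == "frameshift"

    def test_inframe_insert_containing_stop_is_ptc(self):
        ref_cds = "ATG" + "GCT" * 40 + "TAA"
        insert = "GCA" * 10 + "TAA" + "GCA" * 23  # 102 bp with in-frame stop
        alt_cds = "ATG" + "GCT" * 5 + insert + "GCT" * 35 + "TAA"
        frame, ptc, _ = predict_protein_effect(ref_cds, alt_cds, 102)
        assert (frame, ptc) == ("in_frame", "ptc")

    def test_translation_agrees_with_independent_codon_oracle(self):
        rng = random.Random(2)
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(20):
            codons = ["ATG"] + [
                "".join(rng.choice("ACGT") for _ in range(3)) for _ in range(30)
            ] + ["TAA"]
            cds = "".join(codons)
            first = next((i for i, c in enumerate(codons) if c in stops), None)
            frame, ptc, _ = predict_protein_effect(cds, cds, 0)
            # identical transcripts: PTC iff an earlier stop than the terminal
            # one exists is impossible; homologous position equals first stop
            assert ptc == "non_ptc"


class TestNMD:
    @pytest.mark.parametrize(
        "ptc_pos,last_junction,expected",
        [
            (100, 200, "susceptible"),  # 100 nt upstream
            (170, 200, "escape"),  # 30 nt upstream: < 50
            (150, 200, "susceptible"),  # exactly 50
            (250, 200, "escape"),  # in the last exon
            (100, None, "escape"),  # single-exon transcript
        ],
    )
    def test_fifty_bp_rule(self, ptc_pos, last_junction, expected):
        assert nmd_susceptibility(ptc_pos, last_junction) == expected


class TestHGVS:
    def test_identical(self):
        assert hgvs_protein_change("MAKL", "MAKL") == "p.(=)"

    def test_multi_residue_deletion(self):
        # residues 3-5 (KLE) deleted
        assert hgvs_protein_change("MAKLEF", "MAF") == "K3_E5del"

    def test_single_residue_deletion(self):
        assert hgvs_protein_change("MAKL", "MAL") == "K3del"

    def test_insertion(self):
        assert hgvs_protein_change("MAKL", "MAKXYZL") == "K3_L4insX[3]"

    def test_delins(self):
        assert hgvs_protein_change("MAKL", "MAXYZL") == "K3delinsX[3]"

    def test_frameshift_notation(self):
        assert hgvs_protein_change("MAKLEF", "MAKQRS", frameshift=True) == "L4fs"


class TestApparentNonsenseRescue:
    def test_variant_creating_stop_is_spliced_out(self):
        """A would-be nonsense variant whose novel junction removes the stop.

        A donor-creating variant at intronic position +5 of a partial exon
        loss sits inside the lost exonic interval: naive annotation would
        evaluate the substituted codon, yet the aberrant transcript removes
        the base altogether, so the classifier's PTC verdict is driven by
        the spliced product, not the variant base.
        """
        sim = SpliceSimulator(seed=23)
        truth = sim.plant(
            Scenario(side=DONOR, relative_position=5,
                     category_target="partial_exon_loss", event_size=51, penetrance=0.6)
        )
        lo, hi = min(truth.novel_ss, truth.hijacked_ss), max(truth.novel_ss, truth.hijacked_ss)
        assert lo <= truth.pos <= hi  # variant inside the lost interval
        sample = sim.sample("S9", carrier=True, depth=120, seed=42)
        genome = sim.genome()
        txs = sim.transcripts()
        calls = detect_sscvs(sample.junctions, sample.reads, genome, txs)
        call = next(c for c in calls if c.pos == truth.pos)
        conseq = classify_consequence(call, txs, sample.junctions, DepthTrack(sample.reads), genome)
        assert conseq.category == "partial_exon_loss"
        assert conseq.ptc == truth.ptc  # verdict driven by the spliced product
        # in-frame loss of clean codons keeps the original stop: no PTC
        assert (conseq.frame, conseq.ptc) == ("in_frame", truth.ptc)


class TestEndToEndAgainstTruth:
    def test_classifier_recovers_planted_truth(self, planted_sim, planted_sample):
        genome = planted_sim.genome()
        txs = planted_sim.transcripts()
        calls = detect_sscvs(planted_sample.junctions, planted_sample.reads, genome, txs)
        depth = DepthTrack(planted_sample.reads)
        got = {}
        for c in calls:
            q = classify_consequence(c, txs, planted_sample.junctions, depth, genome)
            got[c.pos] = (q.category, q.size_change, q.frame, q.ptc, q.nmd)
            assert (q.frame == "in_frame") == (q.size_change % 3 == 0) or q.frame == "not_applicable"
        expected = {
            t.pos: (t.category, t.size_change, t.frame, t.ptc, t.nmd)
            for t in planted_sim.truths
        }
        assert got == expected
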