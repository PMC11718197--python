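import random

import pytest

from sscv.alu import (
    align_to_reference_alu,
    arm_correspondence,
    element_offset,
    exonized_segments,
    find_clusters,
    intersect_alu,
    map_position,
)
from sscv.consequence import DepthTrack, classify_consequence
from sscv.discovery import detect_sscvs
from sscv.models import (
    ACCEPTOR,
    DONOR,
    AluHit,
    Genome,
    RepeatElement,
    reverse_complement,
)
from sscv.simulate import Scenario, SpliceSimulator, synthetic_alu_consensus
from tests.conftest import make_call, make_junction, make_pnj


def rep(start, end, strand="+", name="AluSx", chrom="chr1"):
    return RepeatElement(chrom, start, end, strand, name, "SINE", "Alu")


def _call(pos, strand="+", novel=None, chrom="chr1"):
    novel = novel or pos + 2
    pnj = make_pnj(make_junction(novel, novel + 300, 9, chrom=chrom), novel + 300,
                   ACCEPTOR, novel, strand=strand)
    return make_call(pos, "A", "G", DONOR, -1, pnj)


class TestIntersect:
    def test_length_threshold(self):
        calls = [(_call(1100), None)]
        assert intersect_alu(calls, [rep(1000, 1149)]) == []  # 150 bp
        hits = intersect_alu(calls, [rep(1000, 1300)])  # 301 bp
        assert len(hits) == 1

    def test_orientation(self):
        hits = intersect_alu([(_call(1100, strand="+"), None)], [rep(1000, 1300, strand="-")])
        assert hits[0].orientation == "antisense"
        hits = intersect_alu([(_call(1100, strand="+"), None)], [rep(1000, 1300, strand="+")])
        assert hits[0].orientation == "sense"

    def test_variant_outside_all_elements(self):
        assert intersect_alu([(_call(50), None)], [rep(1000, 1300)]) == []


class TestAlignmentMap:
    def test_identity(self):
        cons = synthetic_alu_consensus()
        amap = align_to_reference_alu(cons, cons)
        assert amap.identity == 1.0
        assert amap.to_reference(50) == 50

    def test_two_base_deletion_shifts_map(self):
        cons = synthetic_alu_consensus()
        element = cons[:99] + cons[101:]  # delete consensus bases 100-101
        amap = align_to_reference_alu(element, cons)
        assert amap.to_reference(50) == 50
        assert amap.to_reference(120) == 122

    def test_planted_edit_script_recovered(self):
        # oracle: an element synthesized from the consensus with known
        # deletions must map back exactly per the edit script
        cons = synthetic_alu_consensus()
        rng = random.Random(4)
        deletions = sorted(rng.sample(range(30, 250), 3))
        element = cons
        for d in reversed(deletions):
            element = element[:d] + element[d + 1 :]
        amap = align_to_reference_alu(element, cons)
        for epos in (10, 60, 120, 200, 250):
            expected = epos + sum(1 for d in deletions if d < epos)
            got = amap.to_reference(epos + 1)
            assert got == expected + 1

    def test_wrong_strand_low_identity(self):
        cons = synthetic_alu_consensus()
        amap = align_to_reference_alu(reverse_complement(cons), cons)
        assert amap.low_identity

    def test_map_position_monotone_and_gap_absent(self):
        cons = synthetic_alu_consensus()
        element = cons[:99] + "GGGGG" + cons[99:]  # insertion relative to consensus
        amap = align_to_reference_alu(element, cons)
        elem = rep(1000, 1000 + len(element) - 1)
        prev = 0
        for g in range(1000, elem.end + 1):
            a = map_position(amap, elem, g)
            if a is not None:
                assert a > prev
                prev = a


class TestClusters:
    def hit(self, pos, variant_key, side=DONOR, orientation="antisense", family="AluS"):
        call = _call(variant_key[1])
        return AluHit(call=call, element=rep(1, 400), family=family,
                      orientation=orientation, alu_pos_primary_ss=pos)

    def test_threshold_and_distinctness(self):
        hits = []
        for i in range(60):  # 60 distinct variants at consensus position 102
            hits.append(self.hit(102, ("chr1", 5000 + i, "A", "G")))
        for i in range(3):
            hits.append(self.hit(40, ("chr1", 9000 + i, "A", "G")))
        # one recurrent variant seen in 70 samples counts once
        hits += [self.hit(200, ("chr1", 7777, "A", "G"))] * 70
        clusters = find_clusters(hits)
        assert [c.alu_position for c in clusters] == [102]
        assert clusters[0].count == 60

    def test_order_invariance(self):
        rng = random.Random(1)
        hits = [self.hit(102, ("chr1", 5000 + i, "A", "G")) for i in range(55)]
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert find_clusters(hits) == find_clusters(shuffled)

    def test_all_below_threshold(self):
        hits = [self.hit(102, ("chr1", 5000 + i, "A", "G")) for i in range(50)]
        assert find_clusters(hits) == []


class TestArmCorrespondence:
    def test_identical_subsequences_identity_offset(self):
        cons = synthetic_alu_consensus()
        # the first 40 consensus bases are duplicated verbatim in the right
        # arm at offset +135 by construction
        mapping = arm_correspondence(cons, (1, 40), (136, 175))
        for left in range(5, 36):
            assert mapping[left] == left + 135

    def test_indel_between_arms_monotone_shift(self):
        cons = synthetic_alu_consensus()
        mapping = arm_correspondence(cons, (1, 130), (136, 296))
        lefts = sorted(mapping)
        assert all(mapping[a] < mapping[b] for a, b in zip(lefts, lefts[1:]))
        # positions before the right-arm internal insertion map with +135,
        # positions after it with +135+31
        assert mapping[22] == 157
        assert mapping[100] == 100 + 135 + 31


@pytest.fixture(scope="module")
def alu_hits():
    sim = SpliceSimulator(seed=3)
    sim.plant(Scenario(side=DONOR, relative_position=5, category_target="cryptic_exon",
                       event_size=80, in_alu=True, penetrance=1.0))
    genome = sim.genome()
    txs = sim.transcripts()
    sample = sim.sample("S1", carrier=True, depth=100, seed=5)
    calls = detect_sscvs(sample.junctions, sample.reads, genome, txs)
    depth = DepthTrack(sample.reads)
    pairs = [(c, classify_consequence(c, txs, sample.junctions, depth, genome)) for c in calls]
    return sim, intersect_alu(pairs, sim.repeats, genome=genome, ref_alu_seq=sim.alu_consensus)


class TestSimulatedAluExonization:
    def test_hit_is_antisense_with_mapped_positions(self, alu_hits):
        sim, hits = alu_hits
        assert len(hits) == 1
        h = hits[0]
        assert h.orientation == "antisense"
        assert not h.low_identity
        assert h.alu_pos_variant is not None
        assert h.alu_pos_primary_ss is not None

    def test_exonized_segment_confined(self, alu_hits):
        sim, hits = alu_hits
        segments = exonized_segments(hits)
        assert len(segments) == 1
        start, end, count, confined = segments[0]
        assert confined and count == 1
        # the cryptic exon is 80 bp; allowing alignment-level indels its
        # consensus span must be close to that
        assert abs((end - start + 1) - 80) <= 5
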