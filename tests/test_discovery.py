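import itertools
import random

import pytest

from sscv.discovery import (
    ACCEPTOR_ALLOWED,
    DONOR_ALLOWED,
    KIND_ORDER,
    MOTIF_RULES,
    assign_read,
    build_minitranscripts,
    candidate_substitutions,
    detect_sscvs,
    enumerate_candidates,
    mismatch_support,
    population_filter,
    validate_candidate,
)
from sscv.models import (
    ACCEPTOR,
    DONOR,
    AFTable,
    CandidateVariant,
    Genome,
    MiniTranscript,
    ReadRecord,
    SpliceJunction,
    TranscriptModel,
)
from sscv.panel import ControlPanel
from tests.conftest import make_call, make_junction, make_pnj


def oracle_substitutions(window, side):
    """Exhaustive substitution scan with an independent rule check."""
    allowed, required = MOTIF_RULES[side]
    out = []
    for pos in sorted(allowed):
        ref = window.get(pos)
        if ref is None:
            continue
        for alt in "ACGT":
            if alt == ref:
                continue
            if ref in allowed[pos] or alt not in allowed[pos]:
                continue
            mutated = dict(window)
            mutated[pos] = alt
            if all(mutated.get(p) == b for p, b in required):
                out.append((pos, ref, alt))
    return out


class TestMotifEnumeration:
    def test_acceptor_minus3_G_gives_two_candidates(self):
        # consensus-compatible acceptor window except G at -3
        window = {-6: "T", -5: "C", -4: "A", -3: "G", -2: "A", -1: "G", 1: "G"}
        cands = candidate_substitutions(window, ACCEPTOR)
        assert {(p, r, a) for p, r, a in cands} == {(-3, "G", "C"), (-3, "G", "T")}

    def test_donor_dinucleotide_gate(self):
        # exon CA | GCAAGT: the -1 A->G candidate fails because +2 is C (no GT),
        # while C->T at +2 completes GT and is accepted
        window = {-2: "C", -1: "A", 1: "G", 2: "C", 3: "A", 4: "A", 5: "G", 6: "T"}
        cands = candidate_substitutions(window, DONOR)
        assert (2, "C", "T") in cands
        assert all(p != -1 for p, _, _ in cands)

    def test_full_consensus_yields_nothing(self):
        window = {-2: "A", -1: "G", 1: "G", 2: "T", 3: "A", 4: "A", 5: "G", 6: "T"}
        assert candidate_substitutions(window, DONOR) == []

    @pytest.mark.parametrize("side", [DONOR, ACCEPTOR])
    def test_matches_exhaustive_oracle_on_random_windows(self, side):
        rng = random.Random(17)
        positions = sorted(MOTIF_RULES[side][0])
        for _ in range(500):
            window = {p: rng.choice("ACGT") for p in positions}
            assert sorted(candidate_substitutions(window, side)) == sorted(
                oracle_substitutions(window, side)
            )

    def test_enumerate_maps_to_genome_coordinates_both_strands(self):
        # plus strand: novel donor at 31; window = 29..36; -1 position is 30
        seq = ["A"] * 60
        seq[28:36] = list("ATGTAAGT")  # -2 A, -1 T (disallowed), +1.. GTAAGT
        genome = Genome({"chr1": "".join(seq)})
        pnj = make_pnj(make_junction(31, 50), 50, ACCEPTOR, 31, strand="+")
        cands = enumerate_candidates(pnj, genome)
        assert [(c.pos, c.ref_base, c.alt_base, c.relative_position) for c in cands] == [
            (30, "T", "G", -1)
        ]
        # same geometry mirrored on the minus strand: novel donor at 30,
        # intron extends to lower coordinates, motif reads on the reverse
        rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
        mseq = ["T"] * 60
        window = "ATGTAAGT"  # transcript-strand, positions -2..+6
        # genomic positions for minus-strand donor at 30: rel r>0 -> 30-(r-1); r<0 -> 30-r
        coords = {-2: 32, -1: 31, 1: 30, 2: 29, 3: 28, 4: 27, 5: 26, 6: 25}
        for rel, base in zip([-2, -1, 1, 2, 3, 4, 5, 6], window):
            mseq[coords[rel] - 1] = rc[base]
        genome_m = Genome({"chr1": "".join(mseq)})
        pnj_m = make_pnj(make_junction(10, 30), 10, ACCEPTOR, 30, strand="-")
        cands_m = enumerate_candidates(pnj_m, genome_m)
        assert [(c.pos, c.ref_base, c.alt_base, c.relative_position) for c in cands_m] == [
            (31, "A", "C", -1)  # T->G on the transcript strand
        ]


class TestMismatchSupport:
    def make_read(self, base, qual=40, mapq=60, rid="r"):
        return ReadRecord(rid, "AAAA" + base + "AAAA", "chr1", ((96, 104),),
                          mapping_quality=mapq, base_qualities=(qual,) * 9)

    def candidate(self):
        pnj = make_pnj(make_junction(110, 150), 150, ACCEPTOR, 110)
        return CandidateVariant("chr1", 100, "A", "G", DONOR, -1, pnj)

    def test_counts_alt_reads(self):
        reads = [self.make_read("G", rid="a"), self.make_read("G", rid="b"),
                 self.make_read("A", rid="c")]
        assert mismatch_support(self.candidate(), reads) == 2

    def test_quality_gates(self):
        assert mismatch_support(self.candidate(), [self.make_read("G", qual=10)]) == 0
        assert mismatch_support(self.candidate(), [self.make_read("G", mapq=5)]) == 0

    def test_spliced_out_base_not_counted(self):
        read = ReadRecord("r", "AAAAAAAA", "chr1", ((90, 93), (110, 113)))
        assert mismatch_support(self.candidate(), [read]) == 0


def _toy_setup():
    """Genome with annotated intron 1001-1100 and novel junction 1051-1100."""
    rng = random.Random(5)
    seq = [rng.choice("ACGT") for _ in range(1500)]
    genome = Genome({"chr1": "".join(seq)})
    tx = TranscriptModel(transcript_id="T1", gene_id="G", gene_name="G", chrom="chr1",
                         strand="+", exons=((900, 1000), (1101, 1200)))
    pnj = make_pnj(make_junction(1051, 1100, 9), 1100, ACCEPTOR, 1051)
    return genome, tx, pnj


class TestMiniTranscripts:
    def test_exonic_variant_near_boundary_covered_by_all_kinds(self):
        # novel donor inside the exon, close enough to the annotated boundary
        # that the reference window also spans the variant
        genome, tx, _ = _toy_setup()
        pnj = make_pnj(make_junction(995, 1100, 9), 1100, ACCEPTOR, 995)
        ref = genome.base("chr1", 994)
        alt = next(b for b in "ACGT" if b != ref)
        cand = CandidateVariant("chr1", 994, ref, alt, DONOR, -1, pnj)
        minis = build_minitranscripts(cand, genome, [tx])
        kinds = {(m.kind, m.with_sscv) for m in minis}
        assert kinds == set(KIND_ORDER)  # all six
        for m in minis:
            expect = 21 if m.kind == "intron_retention" else 20
            assert len(m.sequence) == expect

    def test_intronic_variant_covered_only_where_retained(self):
        genome, tx, pnj = _toy_setup()
        ref = genome.base("chr1", 1055)  # +5 of the novel donor: spliced out
        alt = next(b for b in "ACGT" if b != ref)
        cand = CandidateVariant("chr1", 1055, ref, alt, DONOR, 5, pnj)
        minis = build_minitranscripts(cand, genome, [tx])
        with_kinds = {m.kind for m in minis if m.with_sscv}
        assert with_kinds == {"intron_retention"}

    def test_no_reference_junction_at_most_four(self):
        genome, tx, pnj = _toy_setup()
        ref = genome.base("chr1", 1050)
        alt = next(b for b in "ACGT" if b != ref)
        cand = CandidateVariant("chr1", 1050, ref, alt, DONOR, -1, pnj)
        minis = build_minitranscripts(cand, genome, [])  # no transcripts
        assert len(minis) <= 4
        assert not any(m.kind == "reference" for m in minis)


class TestAssignRead:
    def minis(self):
        genome, tx, pnj = _toy_setup()
        ref = genome.base("chr1", 1050)
        alt = next(b for b in "ACGT" if b != ref)
        cand = CandidateVariant("chr1", 1050, ref, alt, DONOR, -1, pnj)
        return genome, cand, build_minitranscripts(cand, genome, [tx])

    def test_exact_with_variant_20mer(self):
        genome, cand, minis = self.minis()
        pn_with = next(m for m in minis if m.kind == "primary_novel" and m.with_sscv)
        read = "ACGT" + pn_with.sequence + "TTTT"
        a = assign_read(read, minis)
        assert (a.best_kind, a.with_sscv, a.edit_distance) == ("primary_novel", True, 0)

    def test_reference_without_wins_ties(self):
        # a read matching reference-without exactly also matches nothing better
        genome, cand, minis = self.minis()
        ref_wo = next(m for m in minis if m.kind == "reference" and not m.with_sscv)
        read = "GG" + ref_wo.sequence + "CC"
        a = assign_read(read, minis)
        assert (a.best_kind, a.with_sscv) == ("reference", False)

    def test_guard_rejects_edit_near_variant(self):
        genome, cand, minis = self.minis()
        pn_with = next(m for m in minis if m.kind == "primary_novel" and m.with_sscv)
        # mutate a base 3 bp from the variant offset: every covering template
        # now carries an edit inside the guard window
        o = pn_with.sscv_offset
        seq = list(pn_with.sequence)
        j = o + 3 if o + 3 < len(seq) else o - 3
        seq[j] = next(b for b in "ACGT" if b != seq[j])
        a = assign_read("AA" + "".join(seq) + "TT", minis)
        assert a.best_kind != "primary_novel" or a.with_sscv is not True

    def test_permutation_invariance(self):
        genome, cand, minis = self.minis()
        reads = []
        for m in minis:
            reads.append("AC" + m.sequence + "GT")
        rng = random.Random(0)
        for read in reads:
            base = assign_read(read, minis)
            for _ in range(5):
                shuffled = list(minis)
                rng.shuffle(shuffled)
                again = assign_read(read, shuffled)
                assert (again.best_kind, again.with_sscv, again.edit_distance) == (
                    base.best_kind, base.with_sscv, base.edit_distance,
                )

    def test_short_read_unaligned(self):
        genome, cand, minis = self.minis()
        a = assign_read("ACGTACGT", minis)
        assert a.best_kind is None


class TestValidation:
    def test_counts_with_sscv_assignments(self):
        genome, tx, pnj = _toy_setup()
        ref = genome.base("chr1", 1050)
        alt = next(b for b in "ACGT" if b != ref)
        cand = CandidateVariant("chr1", 1050, ref, alt, DONOR, -1, pnj)
        minis = build_minitranscripts(cand, genome, [tx])
        pn_with = next(m for m in minis if m.kind == "primary_novel" and m.with_sscv)
        ref_wo = next(m for m in minis if m.kind == "reference" and not m.with_sscv)

        def as_read(seq, rid):
            return ReadRecord(rid, seq, "chr1", ((1, len(seq)),))

        variant_reads = [as_read("AC" + pn_with.sequence + "GT", f"v{i}") for i in range(3)]
        ref_reads = [as_read("AC" + ref_wo.sequence + "GT", f"r{i}") for i in range(3)]
        ok, support = validate_candidate(cand, variant_reads + ref_reads, minis)
        assert ok and support == 3
        ok, support = validate_candidate(cand, ref_reads, minis)
        assert (ok, support) == (False, 0)
        assert validate_candidate(cand, [], minis) == (False, 0)


class TestPopulationFilter:
    def _call(self, pos=1000):
        pnj = make_pnj(make_junction(1010, 1100), 1100, ACCEPTOR, 1010)
        return make_call(pos, "A", "G", DONOR, -1, pnj)

    def test_common_dropped_boundary_kept(self):
        table = AFTable({("chr1", 1000, "A", "G"): 0.02, ("chr1", 2000, "A", "G"): 0.01})
        calls = [self._call(1000)]
        assert population_filter(calls, table) == []
        kept = population_filter([self._call(2000)], table)
        assert len(kept) == 1 and kept[0].population_af == 0.01

    def test_absent_kept_with_zero(self):
        kept = population_filter([self._call(3000)], AFTable())
        assert kept[0].population_af == 0.0


class TestDetectEndToEnd:
    def test_planted_variants_recovered_exactly(self, planted_sim, planted_sample):
        genome = planted_sim.genome()
        txs = planted_sim.transcripts()
        calls = detect_sscvs(planted_sample.junctions, planted_sample.reads, genome, txs,
                             sample_id="S1")
        got = {(c.pos, c.variant.ref_base, c.variant.alt_base) for c in calls}
        expected = {(t.pos, t.ref, t.alt) for t in planted_sim.truths}
        assert got == expected

    def test_clean_sample_produces_no_calls(self, planted_sim):
        genome = planted_sim.genome()
        txs = planted_sim.transcripts()
        clean = planted_sim.sample("C1", carrier=False, depth=100, seed=9)
        assert detect_sscvs(clean.junctions, clean.reads, genome, txs) == []

    def test_panel_suppression(self, planted_sim, planted_sample):
        genome = planted_sim.genome()
        txs = planted_sim.transcripts()
        panel = ControlPanel(j.key for j in planted_sample.junctions)
        calls = detect_sscvs(planted_sample.junctions, planted_sample.reads, genome, txs,
                             panel=panel)
        assert calls == []

    def test_common_variant_removed(self, planted_sim, planted_sample):
        genome = planted_sim.genome()
        txs = planted_sim.transcripts()
        table = AFTable()
        hot = planted_sim.truths[0]
        table.add(hot.chrom, hot.pos, hot.ref, hot.alt, 0.5)
        calls = detect_sscvs(planted_sample.junctions, planted_sample.reads, genome, txs,
                             af_table=table)
        assert hot.pos not in {c.pos for c in calls}
        assert len(calls) == len(planted_sim.truths) - 1
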