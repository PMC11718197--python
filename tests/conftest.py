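import pytest

from sscv.models import (
    ACCEPTOR,
    DONOR,
    CandidateVariant,
    Genome,
    PrimaryNovelJunction,
    SpliceJunction,
    SpliceSite,
    SSCVCall,
    TranscriptModel,
)
from sscv.simulate import Scenario, SpliceSimulator


@pytest.fixture
def toy_transcript():
    """Two-exon plus-strand transcript with intron 1001-1100."""
    return TranscriptModel(
        transcript_id="ENST00000000001",
        gene_id="G1",
        gene_name="GENE1",
        chrom="chr1",
        strand="+",
        exons=((900, 1000), (1101, 1200)),
        cds_start=950,
        cds_end=1150,
        tags=frozenset({"basic"}),
    )


def make_junction(start, end, reads=5, chrom="chr1", strand="+"):
    return SpliceJunction(chrom, start, end, strand, reads)


def make_pnj(junction, matching_pos, matching_side, novel_pos, strand="+", source=None):
    novel_side = ACCEPTOR if matching_side == DONOR else DONOR
    return PrimaryNovelJunction(
        junction=junction,
        source=source or junction,
        matching_ss=SpliceSite(matching_pos, matching_side),
        primary_novel_ss=SpliceSite(novel_pos, novel_side),
        matched_transcripts=("ENST00000000001",),
        strand=strand,
    )


def make_call(pos, ref, alt, side, rel, pnj, sample_id="S1"):
    variant = CandidateVariant(
        chrom=pnj.junction.chrom, pos=pos, ref_base=ref, alt_base=alt,
        side=side, relative_position=rel, pnj=pnj,
    )
    return SSCVCall(sample_id=sample_id, variant=variant)


STANDARD_SCENARIOS = [
    Scenario(side=DONOR, relative_position=-1, category_target="partial_exon_loss",
             event_size=50, penetrance=1.0),
    Scenario(side=ACCEPTOR, relative_position=-3, category_target="exon_extension",
             event_size=129, penetrance=1.0),
    Scenario(side=DONOR, relative_position=5, category_target="cryptic_exon",
             event_size=102, penetrance=1.0),
    Scenario(side=ACCEPTOR, relative_position=1, category_target="partial_exon_loss",
             event_size=48, penetrance=1.0),
]


@pytest.fixture(scope="session")
def planted_sim():
    """One simulator with the four standard scenarios planted."""
    sim = SpliceSimulator(seed=11)
    for sc in STANDARD_SCENARIOS:
        sim.plant(sc)
    return sim


@pytest.fixture(scope="session")
def planted_sample(planted_sim):
    return planted_sim.sample("S1", carrier=True, depth=100, seed=5)
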