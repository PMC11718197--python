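"""Discovery and validation of splice-site creating variants.

For each primary novel junction we enumerate the single-base substitutions
that would move the sequence at the novel splice site toward the consensus
motif (donor ``AG|GTRAGT``, acceptor ``YYNYAG|R``, ``|`` the exon-intron
boundary), require mismatch support in the aligned reads, and validate each
candidate by realigning nearby reads against up to six "mini-transcripts"
(primary novel / reference / intron retention, each with and without the
variant).  A candidate survives when at least one read prefers a
with-variant template.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import edlib

from sscv.models import (
    ACCEPTOR,
    DONOR,
    AFTable,
    CandidateVariant,
    Genome,
    MiniTranscript,
    PrimaryNovelJunction,
    ReadAssignment,
    ReadRecord,
    SpliceJunction,
    SSCVCall,
    TranscriptModel,
    reverse_complement,
)
from sscv.panel import ControlPanel
from sscv.screen import find_primary_novel_junctions, screen

logger = logging.getLogger(__name__)

# Consensus splice motifs in transcript direction.  Negative positions are
# exonic for donors and intronic for acceptors; the boundary sits between
# -1 and +1.  The spliceosomally essential dinucleotide (GT / AG) must hold
# after the substitution.
DONOR_ALLOWED: dict[int, frozenset[str]] = {
    -2: frozenset("A"), -1: frozenset("G"),
    1: frozenset("G"), 2: frozenset("T"), 3: frozenset("AG"),
    4: frozenset("A"), 5: frozenset("G"), 6: frozenset("T"),
}
DONOR_REQUIRED: tuple[tuple[int, str], ...] = ((1, "G"), (2, "T"))

ACCEPTOR_ALLOWED: dict[int, frozenset[str]] = {
    -6: frozenset("CT"), -5: frozenset("CT"), -4: frozenset("ACGT"),
    -3: frozenset("CT"), -2: frozenset("A"), -1: frozenset("G"),
    1: frozenset("AG"),
}
ACCEPTOR_REQUIRED: tuple[tuple[int, str], ...] = ((-2, "A"), (-1, "G"))

MOTIF_RULES = {
    DONOR: (DONOR_ALLOWED, DONOR_REQUIRED),
    ACCEPTOR: (ACCEPTOR_ALLOWED, ACCEPTOR_REQUIRED),
}

# Canonical tie-break order for read assignment (most conservative first).
KIND_ORDER: tuple[tuple[str, bool], ...] = (
    ("reference", False),
    ("intron_retention", False),
    ("primary_novel", False),
    ("reference", True),
    ("intron_retention", True),
    ("primary_novel", True),
)


def candidate_substitutions(window: dict[int, str], side: str) -> list[tuple[int, str, str]]:
    """Motif-improving substitutions on a transcript-strand window.

    ``window`` maps signed relative positions to the reference base on the
    transcript strand.  Returns (relative_position, ref, alt) for every
    substitution where the reference base is outside the allowed set, the
    alternative is inside it, and the essential dinucleotide holds after the
    (single) substitution.
    """
    allowed, required = MOTIF_RULES[side]
    out = []
    for pos, bases in allowed.items():
        ref = window.get(pos)
        if ref is None or ref in bases:
            continue
        for alt in sorted(bases):
            if alt == ref:
                continue
            mutated = dict(window)
            mutated[pos] = alt
            if all(mutated.get(rp) == rb for rp, rb in required):
                out.append((pos, ref, alt))
    return out


def _relative_to_genomic(ss_pos: int, side: str, strand: str, rel: int) -> int:
    """Genomic coordinate of a signed motif position around a novel site."""
    if side == DONOR:
        # +1 is the first intron base = the donor coordinate itself
        step = rel - 1 if rel > 0 else rel
    else:
        # -1 is the last intron base = the acceptor coordinate itself
        step = rel + 1 if rel < 0 else rel
    return ss_pos + step if strand == "+" else ss_pos - step


def enumerate_candidates(
    pnj: PrimaryNovelJunction, genome: Genome, rule: Optional[str] = None
) -> list[CandidateVariant]:
    """All substitutions that bring the novel splice site closer to consensus."""
    side = rule or pnj.primary_novel_ss.side
    strand = pnj.strand
    ss = pnj.primary_novel_ss.pos
    allowed, _ = MOTIF_RULES[side]
    window: dict[int, str] = {}
    positions: dict[int, int] = {}
    for rel in allowed:
        gpos = _relative_to_genomic(ss, side, strand, rel)
        try:
            base = genome.fetch(pnj.junction.chrom, gpos, gpos, strand)
        except (KeyError, ValueError):
            logger.warning("motif window position %s:%d off contig, skipped", pnj.junction.chrom, gpos)
            continue
        window[rel] = base
        positions[rel] = gpos
    out = []
    for rel, ref_t, alt_t in candidate_substitutions(window, side):
        gpos = positions[rel]
        if strand == "+":
            ref_g, alt_g = ref_t, alt_t
        else:
            ref_g, alt_g = reverse_complement(ref_t), reverse_complement(alt_t)
        out.append(
            CandidateVariant(
                chrom=pnj.junction.chrom, pos=gpos, ref_base=ref_g, alt_base=alt_g,
                side=side, relative_position=rel, pnj=pnj,
            )
        )
    out.sort(key=lambda c: (c.pos, c.alt_base))
    return out


def mismatch_support(
    candidate: CandidateVariant,
    reads: Sequence[ReadRecord],
    min_baseq: int = 15,
    min_mapq: int = 20,
) -> int:
    """Reads showing the alternative base at the candidate position."""
    n = 0
    for read in reads:
        if read.chrom != candidate.chrom or read.mapping_quality < min_mapq:
            continue
        hit = read.base_at(candidate.pos)
        if hit is None:
            continue
        base, qual = hit
        if base == candidate.alt_base and qual >= min_baseq:
            n += 1
    return n


def _with_variant(seq: str, offset: int, alt: str) -> str:
    return seq[:offset] + alt + seq[offset + 1 :]


def _junction_window(
    genome: Genome, chrom: str, intron_start: int, intron_end: int, flank: int = 10
) -> Optional[tuple[str, list[int]]]:
    """20-mer across a junction plus the genomic position of each base."""
    try:
        left = genome.fetch(chrom, intron_start - flank, intron_start - 1)
        right = genome.fetch(chrom, intron_end + 1, intron_end + flank)
    except (KeyError, ValueError):
        return None
    positions = list(range(intron_start - flank, intron_start)) + list(
        range(intron_end + 1, intron_end + flank + 1)
    )
    return left + right, positions


def _reference_junctions(
    pnj: PrimaryNovelJunction, transcripts: Sequence[TranscriptModel]
) -> list[tuple[int, int, int]]:
    """Annotated introns sharing the matching splice site.

    Returns (intron_start, intron_end, longest transcript length) per
    distinct intron.
    """
    edge_is_start = pnj.matching_edge_is_start
    target = pnj.matching_ss.pos
    found: dict[tuple[int, int], int] = {}
    for tx in transcripts:
        if tx.chrom != pnj.junction.chrom:
            continue
        for s, e in tx.introns():
            terminal = s if edge_is_start else e
            if terminal == target:
                key = (s, e)
                found[key] = max(found.get(key, 0), tx.length)
    return [(s, e, length) for (s, e), length in sorted(found.items())]


def build_minitranscripts(
    candidate: CandidateVariant,
    genome: Genome,
    transcripts: Sequence[TranscriptModel],
    flank: int = 10,
) -> list[MiniTranscript]:
    """Up to six realignment templates for one candidate variant.

    Sequences are on the genome plus strand (matching stored read
    sequences).  A with-variant version is emitted only when the template
    window covers the variant position.
    """
    pnj = candidate.pnj
    chrom = candidate.chrom
    pos = candidate.pos
    minis: list[MiniTranscript] = []

    def add(kind: str, seq: str, positions: Optional[list[int]], tx_len: int = 0):
        offset = positions.index(pos) if positions and pos in positions else None
        minis.append(MiniTranscript(kind, False, seq, offset, tx_len))
        if offset is not None:
            minis.append(
                MiniTranscript(kind, True, _with_variant(seq, offset, candidate.alt_base), offset, tx_len)
            )

    window = _junction_window(genome, chrom, pnj.junction.intron_start, pnj.junction.intron_end, flank)
    if window is not None:
        add("primary_novel", *window)

    for s, e, tx_len in _reference_junctions(pnj, transcripts):
        window = _junction_window(genome, chrom, s, e, flank)
        if window is not None:
            add("reference", *window, tx_len)

    try:
        seq = genome.fetch(chrom, pos - flank, pos + flank)
        add("intron_retention", seq, list(range(pos - flank, pos + flank + 1)))
    except (KeyError, ValueError):
        pass
    return minis


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _edit_query_positions(cigar: str) -> list[int]:
    """Query (mini) offsets of all non-match operations in an edlib CIGAR."""
    out = []
    q = 0
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in ("=", "M"):
            q += n
        elif op == "X":
            out.extend(range(q, q + n))
            q += n
        elif op == "I":  # consumes query only
            out.extend(range(q, q + n))
            q += n
        elif op == "D":  # consumes target only; locate at current query offset
            out.append(min(q, max(q - 1, 0)))
    return out


def _align_mini(read_seq: str, mini: MiniTranscript, max_edit: int, guard_bp: int) -> Optional[int]:
    """Edit distance of the best qualifying infix alignment, or None."""
    if len(read_seq) < len(mini.sequence):
        return None
    res = edlib.align(mini.sequence, read_seq, mode="HW", task="path", k=max_edit)
    dist = res["editDistance"]
    if dist < 0:
        return None
    if mini.sscv_offset is not None and dist > 0:
        edits = _edit_query_positions(res["cigar"] or "")
        if any(abs(e - mini.sscv_offset) <= guard_bp for e in edits):
            return None
    return dist


def assign_read(
    read: ReadRecord | str,
    minis: Sequence[MiniTranscript],
    max_edit: int = 2,
    guard_bp: int = 5,
) -> ReadAssignment:
    """Assign a read to its best mini-transcript.

    The template must be found within the read (infix alignment) with edit
    distance <= ``max_edit`` and with no edit within ``guard_bp`` of the
    variant position for templates covering it.  Ties on edit distance are
    broken by the fixed kind order (reference-without first, primary-novel-
    with last), and among several reference templates by the longest source
    transcript — never by input order.
    """
    if isinstance(read, ReadRecord):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = "read", read
    best = None
    for mini in minis:
        dist = _align_mini(seq, mini, max_edit, guard_bp)
        if dist is None:
            continue
        key = (dist, KIND_ORDER.index((mini.kind, mini.with_sscv)), -mini.ref_transcript_length, mini.sequence)
        if best is None or key < best[0]:
            best = (key, mini, dist)
    if best is None:
        return ReadAssignment(read_id, None, None, None)
    _, mini, dist = best
    return ReadAssignment(read_id, mini.kind, mini.with_sscv, dist)


def validate_candidate(
    candidate: CandidateVariant,
    reads: Sequence[ReadRecord],
    minis: Sequence[MiniTranscript],
    max_edit: int = 2,
    guard_bp: int = 5,
) -> tuple[bool, int]:
    """Count reads preferring a with-variant template; valid when >= 1."""
    support = 0
    for read in reads:
        assignment = assign_read(read, minis, max_edit=max_edit, guard_bp=guard_bp)
        if assignment.with_sscv:
            support += 1
    return support >= 1, support


def population_filter(
    calls: Sequence[SSCVCall], af_table: Optional[AFTable], max_af: float = 0.01
) -> list[SSCVCall]:
    """Drop common variants (population allele frequency above ``max_af``)."""
    if af_table is None:
        return list(calls)
    out = []
    for call in calls:
        v = call.variant
        af = af_table.get(v.chrom, v.pos, v.ref_base, v.alt_base)
        if af > max_af:
            continue
        out.append(replace(call, population_af=af, variant=replace(v, population_af=af)))
    return out


@dataclass
class DetectConfig:
    """Thresholds of the discovery pipeline (defaults per the method)."""

    margin: int = 5
    min_junction_reads: int = 3
    min_fraction: float = 0.05
    max_intersect: int = 4
    min_mismatch_reads: int = 2
    min_baseq: int = 15
    min_mapq: int = 20
    max_edit: int = 2
    guard_bp: int = 5
    max_af: float = 0.01
    qc_max_calls_per_sample: int = 50


def detect_sscvs(
    junctions: Sequence[SpliceJunction],
    reads: Sequence[ReadRecord],
    genome: Genome,
    transcripts: Sequence[TranscriptModel],
    panel: Optional[ControlPanel] = None,
    af_table: Optional[AFTable] = None,
    sample_id: str = "sample",
    config: Optional[DetectConfig] = None,
) -> list[SSCVCall]:
    """Full per-sample discovery pipeline.

    Junction screening -> motif-improving candidate enumeration -> mismatch
    support -> mini-transcript realignment validation -> common-variant
    filtering.  A variant explained by several primary novel junctions is
    reported once, keeping the junction with the most supporting reads.
    """
    cfg = config or DetectConfig()
    pnjs = find_primary_novel_junctions(junctions, transcripts, margin=cfg.margin)
    kept = screen(
        pnjs, junctions, panel,
        min_reads=cfg.min_junction_reads,
        min_fraction=cfg.min_fraction,
        max_intersect=cfg.max_intersect,
    )
    calls: dict[tuple, SSCVCall] = {}
    for pnj in kept:
        for candidate in enumerate_candidates(pnj, genome):
            mm = mismatch_support(candidate, reads, cfg.min_baseq, cfg.min_mapq)
            if mm < cfg.min_mismatch_reads:
                continue
            minis = build_minitranscripts(candidate, genome, transcripts)
            nearby = [r for r in reads if r.chrom == candidate.chrom and r.covers(candidate.pos)]
            valid, support = validate_candidate(
                candidate, nearby, minis, max_edit=cfg.max_edit, guard_bp=cfg.guard_bp
            )
            if not valid:
                continue
            candidate = replace(candidate, mismatch_reads=mm, realign_support=support)
            call = SSCVCall(sample_id=sample_id, variant=candidate)
            key = candidate.key
            prev = calls.get(key)
            if prev is None or candidate.pnj.unique_reads > prev.variant.pnj.unique_reads:
                calls[key] = call
    out = population_filter(list(calls.values()), af_table, max_af=cfg.max_af)
    out.sort(key=lambda c: (c.chrom, c.pos, c.variant.alt_base, c.sample_id))
    logger.info("detect_sscvs[%s]: %d calls", sample_id, len(out))
    return out


def flag_sample_qc(calls: Sequence[SSCVCall], max_calls: int = 50) -> bool:
    """Post-hoc sample QC: an extreme number of calls suggests contamination."""
    return len(calls) > max_calls
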