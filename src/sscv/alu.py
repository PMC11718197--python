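"""Positional analysis of SSCVs inside Alu elements.

Alu retrotransposons carry near-splice-site sequences, so single-base
substitutions inside them frequently create functional splice motifs
("Alu exonization").  This module intersects SSCVs with RepeatMasker Alu
elements, aligns each element to a reference Alu consensus so that variant
and splice-site positions can be expressed in consensus coordinates, calls
hotspot clusters of recurrent positions, tabulates the exonized segments of
cryptic-exon events, and aligns the two arms of the dimeric consensus to
each other to reveal corresponding hotspot positions.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import replace
from typing import Optional, Sequence

from Bio import Align
from intervaltree import IntervalTree

from sscv.models import (
    AluCluster,
    AluHit,
    ConsequenceCall,
    Genome,
    RepeatElement,
    SSCVCall,
    alu_family,
    reverse_complement,
)

logger = logging.getLogger(__name__)


class AlignmentMap:
    """Monotone partial mapping between element positions and consensus positions.

    Positions are 1-based offsets: into the element (consensus orientation)
    on one side and into the reference Alu on the other.  Columns aligned to
    a gap map to nothing.
    """

    def __init__(self, pairs: Sequence[tuple[int, int]], score: float = 0.0, identity: float = 1.0):
        self._fwd = dict(pairs)
        self._rev = {b: a for a, b in pairs}
        prev = None
        for a, b in sorted(self._fwd.items()):
            if prev is not None and b <= prev:
                raise ValueError("alignment map must be strictly increasing")
            prev = b
        self.score = score
        self.identity = identity

    def to_reference(self, element_pos: int) -> Optional[int]:
        return self._fwd.get(element_pos)

    def to_element(self, ref_pos: int) -> Optional[int]:
        return self._rev.get(ref_pos)

    def __len__(self) -> int:
        return len(self._fwd)


def _pairwise_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap_open: float = -5.0, gap_extend: float = -2.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_to_reference_alu(
    element_seq: str,
    ref_alu_seq: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    min_identity: float = 0.5,
) -> AlignmentMap:
    """Globally align an element (consensus orientation) to the reference Alu.

    Scoring defaults suit the ~85% identity of genomic Alu copies (gap
    penalties stiff enough that an unrelated sequence cannot inflate its
    identity by gapping around mismatches).  The map covers matched columns
    only; identity — matches over all alignment columns, gaps included —
    below ``min_identity`` flags the alignment as low quality (callers drop
    such hits from cluster counts).
    """
    aligner = _pairwise_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(element_seq.upper(), ref_alu_seq.upper())[0]
    pairs = []
    n_match = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for i in range(qe - qs):
            a, b = qs + i, ts + i
            pairs.append((a + 1, b + 1))
            if element_seq[a].upper() == ref_alu_seq[b].upper():
                n_match += 1
    identity = n_match / max(aln.shape[1], 1)  # gap columns count against
    amap = AlignmentMap(pairs, score=aln.score, identity=identity)
    if identity < min_identity:
        logger.info("alignment identity %.2f below %.2f", identity, min_identity)
    amap.low_identity = identity < min_identity
    return amap


def element_offset(element: RepeatElement, genomic_pos: int) -> int:
    """1-based offset of a genomic position within the element, consensus orientation."""
    if not element.start <= genomic_pos <= element.end:
        raise ValueError("position outside element")
    if element.strand == "-":
        return element.end - genomic_pos + 1
    return genomic_pos - element.start + 1


def map_position(alnmap: AlignmentMap, element: RepeatElement, genomic_pos: int) -> Optional[int]:
    """Reference-Alu coordinate of a genomic position, None when unaligned/gapped."""
    if not element.start <= genomic_pos <= element.end:
        return None
    return alnmap.to_reference(element_offset(element, genomic_pos))


def intersect_alu(
    calls: Sequence[tuple[SSCVCall, Optional[ConsequenceCall]]],
    repeats: Sequence[RepeatElement],
    min_len: int = 200,
    genome: Optional[Genome] = None,
    ref_alu_seq: Optional[str] = None,
    transcript_strands: Optional[dict[str, str]] = None,
) -> list[AluHit]:
    """Place SSCVs inside Alu elements of at least ``min_len`` bp.

    Orientation is sense when element strand equals the transcript strand of
    the call.  When a genome and a reference Alu sequence are supplied, each
    hit also gets consensus coordinates for the variant, the primary novel
    splice site, and (cryptic exons) the secondary splice site.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, rep in enumerate(repeats):
        if rep.length >= min_len:
            trees[rep.chrom][rep.start : rep.end + 1] = i

    maps: dict[int, AlignmentMap] = {}
    hits = []
    for call, conseq in calls:
        pos = call.pos
        for iv in sorted(trees[call.chrom][pos]):
            rep = repeats[iv.data]
            strand = call.variant.pnj.strand
            if transcript_strands and conseq and conseq.reference_transcript_id:
                strand = transcript_strands.get(conseq.reference_transcript_id, strand)
            orientation = None
            if strand in ("+", "-"):
                orientation = "sense" if rep.strand == strand else "antisense"
            hit = AluHit(
                call=call, element=rep, family=alu_family(rep.rep_name),
                orientation=orientation, consequence=conseq,
            )
            if genome is not None and ref_alu_seq is not None:
                if iv.data not in maps:
                    seq = genome.fetch(rep.chrom, rep.start, rep.end, "+")
                    if rep.strand == "-":
                        seq = reverse_complement(seq)
                    maps[iv.data] = align_to_reference_alu(seq, ref_alu_seq)
                amap = maps[iv.data]
                exon_bounds = (None, None)
                if (
                    conseq is not None
                    and conseq.category == "cryptic_exon"
                    and conseq.changed_interval is not None
                ):
                    lo, hi = conseq.changed_interval
                    mapped = sorted(
                        p for p in (map_position(amap, rep, lo), map_position(amap, rep, hi))
                        if p is not None
                    )
                    if len(mapped) == 2:
                        exon_bounds = (mapped[0], mapped[1])
                    elif len(mapped) == 1:
                        exon_bounds = (mapped[0], None)
                hit = replace(
                    hit,
                    low_identity=getattr(amap, "low_identity", False),
                    alu_pos_variant=map_position(amap, rep, pos),
                    alu_pos_primary_ss=map_position(
                        amap, rep, call.variant.pnj.primary_novel_ss.pos
                    ),
                    alu_pos_secondary_ss=(
                        map_position(amap, rep, conseq.secondary_ss)
                        if conseq and conseq.secondary_ss is not None
                        else None
                    ),
                    alu_exon_start=exon_bounds[0],
                    alu_exon_end=exon_bounds[1],
                )
            hits.append(hit)
    return hits


def find_clusters(hits: Sequence[AluHit], min_count: int = 51) -> list[AluCluster]:
    """Hotspot positions of primary novel splice sites on the consensus.

    Counts distinct SSCVs (a variant recurring in many samples counts once)
    per (consensus position, side, orientation); clusters have
    count >= ``min_count`` (i.e. strictly more than min_count - 1).
    Low-identity alignments are excluded.
    """
    groups: dict[tuple[int, str, str], dict[tuple, str]] = defaultdict(dict)
    for hit in hits:
        if hit.low_identity or hit.alu_pos_primary_ss is None or hit.orientation is None:
            continue
        key = (hit.alu_pos_primary_ss, hit.call.variant.side, hit.orientation)
        groups[key][hit.call.variant.key] = hit.family
    out = []
    for (pos, side, orientation), variants in sorted(groups.items()):
        if len(variants) >= min_count:
            fam = Counter(variants.values())
            out.append(
                AluCluster(
                    alu_position=pos, count=len(variants), side=side,
                    orientation=orientation,
                    family_counts=tuple(sorted(fam.items())),
                )
            )
    return out


def exonized_segments(
    cryptic_hits: Sequence[AluHit],
) -> list[tuple[Optional[int], Optional[int], int, bool]]:
    """Consensus-coordinate spans of the novel exons of cryptic-exon hits.

    Returns (alu_start, alu_end, count, confined) rows sorted by position;
    ``confined`` means both exon bounds lie inside the element and mapped to
    consensus positions.  Identical segments aggregate with a count.
    """
    counter: Counter = Counter()
    for hit in cryptic_hits:
        conseq = hit.consequence
        if conseq is None or conseq.category != "cryptic_exon" or conseq.changed_interval is None:
            continue
        lo, hi = conseq.changed_interval
        rep = hit.element
        inside = rep.start <= lo and hi <= rep.end
        confined = inside and hit.alu_exon_start is not None and hit.alu_exon_end is not None
        counter[(hit.alu_exon_start, hit.alu_exon_end, confined)] += 1
    return [
        (start, end, count, confined)
        for (start, end, confined), count in sorted(
            counter.items(), key=lambda kv: (kv[0][0] is None, kv[0][0] or 0, kv[0][1] or 0)
        )
    ]


def arm_correspondence(
    ref_alu_seq: str,
    left_arm_range: tuple[int, int],
    right_arm_range: tuple[int, int],
    **aligner_kwargs,
) -> dict[int, int]:
    """Map corresponding positions between the two arms of the dimeric consensus.

    Both arm subsequences are reverse-complemented before alignment (the
    antisense-donor hotspots live on the reverse strand), and the returned
    mapping is expressed in forward coordinates of the full reference Alu:
    left-arm position -> corresponding right-arm position.
    """
    l1, l2 = left_arm_range
    r1, r2 = right_arm_range
    left = reverse_complement(ref_alu_seq[l1 - 1 : l2])
    right = reverse_complement(ref_alu_seq[r1 - 1 : r2])
    aligner = _pairwise_aligner(**aligner_kwargs)
    aln = aligner.align(left, right)[0]
    mapping = {}
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for i in range(qe - qs):
            # offset i within the reverse-complemented subsequences; convert
            # back to forward coordinates of the full consensus
            left_pos = l2 - (qs + i)
            right_pos = r2 - (ts + i)
            mapping[left_pos] = right_pos
    return dict(sorted(mapping.items()))
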