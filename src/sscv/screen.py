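"""Screening of one sample's junctions for primary novel splicing junctions.

A primary novel junction has one edge matching an annotated exon-intron
boundary (within a small margin, to absorb alignment sliding at repeated
bases) and one edge matching no annotated boundary — the signature of a
splice site created de novo.  Four exclusion filters then remove weak or
unremarkable junctions: a minimum read count, membership in a control
panel, a minimum share of the reads at the matching splice site, and a cap
on the number of intersecting junctions.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional, Sequence

from intervaltree import IntervalTree

from sscv.models import (
    ACCEPTOR,
    DONOR,
    PrimaryNovelJunction,
    SpliceJunction,
    SpliceSite,
    TranscriptModel,
)
from sscv.panel import ControlPanel

logger = logging.getLogger(__name__)


class BoundaryIndex:
    """Annotated intron-terminal coordinates indexed per chromosome.

    ``starts[chrom][pos]`` lists transcripts with an intron starting at pos
    (genomic-left intron terminal); ``ends`` likewise for the genomic-right
    terminal.  Whether a terminal is a donor or an acceptor depends on the
    transcript strand.
    """

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.starts: dict[str, dict[int, list[TranscriptModel]]] = defaultdict(lambda: defaultdict(list))
        self.ends: dict[str, dict[int, list[TranscriptModel]]] = defaultdict(lambda: defaultdict(list))
        for tx in transcripts:
            for s, e in tx.introns():
                self.starts[tx.chrom][s].append(tx)
                self.ends[tx.chrom][e].append(tx)

    def annotated(self, chrom: str, pos: int, edge: str) -> list[TranscriptModel]:
        table = self.starts if edge == "start" else self.ends
        return table[chrom].get(pos, [])

    def nearby(self, chrom: str, pos: int, edge: str, margin: int):
        """Candidate annotated coordinates within margin, as (offset, coord, txs).

        Sorted by |offset| then coordinate, so the first entry is the
        canonical match.
        """
        table = self.starts if edge == "start" else self.ends
        hits = []
        for coord in range(pos - margin, pos + margin + 1):
            txs = table[chrom].get(coord)
            if txs:
                hits.append((coord - pos, coord, txs))
        hits.sort(key=lambda h: (abs(h[0]), h[1]))
        return hits


def _edge_sides(edge: str, strand: str) -> tuple[str, str]:
    """(side of this edge, side of the opposite edge) for a transcript strand."""
    if edge == "start":
        this = DONOR if strand == "+" else ACCEPTOR
    else:
        this = ACCEPTOR if strand == "+" else DONOR
    other = ACCEPTOR if this == DONOR else DONOR
    return this, other


def find_primary_novel_junctions(
    junctions: Sequence[SpliceJunction],
    transcripts: Sequence[TranscriptModel],
    margin: int = 5,
) -> list[PrimaryNovelJunction]:
    """Identify junctions with exactly one annotated edge.

    When the matching edge is within ``margin`` of an annotated boundary but
    not exact, both intron coordinates are shifted by the same offset
    (preserving intron length), so the matching edge lands exactly on the
    annotation.  Junctions with both edges annotated, with both edges merely
    near (but not on) annotations, or with neither edge near an annotation
    are dropped.
    """
    index = BoundaryIndex(transcripts)
    out = []
    n_dropped = 0
    for j in junctions:
        start_exact = index.annotated(j.chrom, j.intron_start, "start")
        end_exact = index.annotated(j.chrom, j.intron_end, "end")
        if start_exact and end_exact:
            n_dropped += 1
            continue
        start_near = index.nearby(j.chrom, j.intron_start, "start", margin)
        end_near = index.nearby(j.chrom, j.intron_end, "end", margin)
        if start_exact or end_exact:
            matching_edge = "start" if start_exact else "end"
            offset = 0
            matched = start_exact or end_exact
        elif start_near and end_near:
            # both edges merely near annotations: treated as an annotated
            # junction observed with alignment slippage
            n_dropped += 1
            continue
        elif start_near or end_near:
            hits = start_near or end_near
            matching_edge = "start" if start_near else "end"
            offset, _, matched = hits[0]
        else:
            n_dropped += 1
            continue

        adj = SpliceJunction(
            chrom=j.chrom,
            intron_start=j.intron_start + offset,
            intron_end=j.intron_end + offset,
            strand=j.strand,
            unique_reads=j.unique_reads,
        )
        novel_edge = "end" if matching_edge == "start" else "start"
        novel_pos = adj.intron_end if novel_edge == "end" else adj.intron_start
        # after adjustment the novel edge must still be unannotated
        if index.annotated(j.chrom, novel_pos, novel_edge):
            n_dropped += 1
            continue

        # resolve strand from matched transcripts; prefer the SJ strand code
        # when transcripts on both strands share the boundary
        strands = sorted({tx.strand for tx in matched})
        strand = strands[0] if len(strands) == 1 else (
            j.strand if j.strand in strands else strands[0]
        )
        matched_here = sorted(tx.transcript_id for tx in matched if tx.strand == strand)
        matching_side, novel_side = _edge_sides(matching_edge, strand)
        matching_pos = adj.intron_start if matching_edge == "start" else adj.intron_end
        out.append(
            PrimaryNovelJunction(
                junction=adj,
                source=j,
                matching_ss=SpliceSite(matching_pos, matching_side),
                primary_novel_ss=SpliceSite(novel_pos, novel_side),
                matched_transcripts=tuple(matched_here),
                strand=strand,
                adjustment_offset=offset,
            )
        )
    logger.info(
        "find_primary_novel_junctions: %d candidates, %d junctions dropped",
        len(out), n_dropped,
    )
    return out


def sharing_read_total(pnj: PrimaryNovelJunction, junctions: Sequence[SpliceJunction]) -> int:
    """Total supporting reads of junctions sharing the matching splice site.

    Junctions share the site when their same-side intron terminal equals the
    matching coordinate; the primary novel junction itself always counts
    (even if its raw record was position-adjusted onto the boundary).
    """
    edge_is_start = pnj.matching_edge_is_start
    target = pnj.matching_ss.pos
    total = 0
    seen_source = False
    for j in junctions:
        if j.chrom != pnj.junction.chrom:
            continue
        terminal = j.intron_start if edge_is_start else j.intron_end
        if terminal == target:
            total += j.unique_reads
            if j == pnj.source:
                seen_source = True
    if not seen_source:
        total += pnj.source.unique_reads
    return total


def intersecting_count(pnj: PrimaryNovelJunction, junctions: Sequence[SpliceJunction]) -> int:
    """Number of other junctions whose intron interval overlaps by >= 1 bp."""
    n = 0
    for j in junctions:
        if j == pnj.source:
            continue
        if j.overlaps(pnj.source):
            n += 1
    return n


class _JunctionOverlapIndex:
    """Interval tree per chromosome for fast intersect counting."""

    def __init__(self, junctions: Sequence[SpliceJunction]):
        self.trees: dict[str, IntervalTree] = {}
        by_chrom: dict[str, list[SpliceJunction]] = defaultdict(list)
        for j in junctions:
            by_chrom[j.chrom].append(j)
        for chrom, js in by_chrom.items():
            self.trees[chrom] = IntervalTree.from_tuples(
                (j.intron_start, j.intron_end + 1, i) for i, j in enumerate(js)
            )
            by_chrom[chrom] = js
        self.by_chrom = by_chrom

    def count_overlapping(self, j: SpliceJunction) -> int:
        tree = self.trees.get(j.chrom)
        if tree is None:
            return 0
        hits = tree.overlap(j.intron_start, j.intron_end + 1)
        n = len(hits)
        for h in hits:
            if self.by_chrom[j.chrom][h.data] == j:
                n -= 1
                break
        return n


def screen(
    pnjs: Sequence[PrimaryNovelJunction],
    junctions: Sequence[SpliceJunction],
    panel: Optional[ControlPanel] = None,
    min_reads: int = 3,
    min_fraction: float = 0.05,
    max_intersect: int = 4,
) -> list[PrimaryNovelJunction]:
    """Apply the four exclusion filters to primary novel junctions.

    Retained junctions have >= min_reads supporting reads, are absent from
    the control panel (both adjusted and raw keys checked), carry at least
    ``min_fraction`` of all reads at their matching splice site, and overlap
    at most ``max_intersect`` other junctions.
    """
    overlap_index = _JunctionOverlapIndex(junctions)
    out = []
    for pnj in pnjs:
        if pnj.unique_reads < min_reads:
            continue
        if panel is not None and (panel.contains(pnj.junction) or panel.contains(pnj.source)):
            continue
        total = sharing_read_total(pnj, junctions)
        if total > 0 and pnj.unique_reads / total < min_fraction:
            continue
        if overlap_index.count_overlapping(pnj.source) > max_intersect:
            continue
        out.append(pnj)
    logger.info("screen: %d of %d primary novel junctions retained", len(out), len(pnjs))
    return out
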