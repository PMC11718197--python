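"""Splicing- and protein-level consequences of splice-site creating variants.

Given a validated SSCV and its primary novel junction, a reference
transcript is chosen (MANE Select > MANE Plus Clinical > largest), the
affected exon and the hijacked splice site are located, and the event is
classified as partial exon loss, exon extension, cryptic exon inclusion or
ambiguous.  The altered mature transcript is then reconstructed to decide
frame (size change modulo 3), premature termination (first stop before the
homologous original stop) and NMD susceptibility by the 50 bp rule, and to
produce an HGVS-style protein change with novel residues rendered as X[n].

All before/after comparisons are made in transcript direction, so
minus-strand transcripts are handled by mirroring, never by re-deriving the
rules.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter, defaultdict
from typing import Callable, Optional, Sequence

from Bio.Seq import Seq

from sscv.models import (
    ACCEPTOR,
    DONOR,
    ConsequenceCall,
    Genome,
    ReadRecord,
    SpliceJunction,
    SpliceSite,
    SSCVCall,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

PARTIAL_EXON_LOSS = "partial_exon_loss"
EXON_EXTENSION = "exon_extension"
CRYPTIC_EXON = "cryptic_exon"
AMBIGUOUS = "ambiguous"


# ---------------------------------------------------------------------------
# Reference transcript


def select_reference_transcript(
    matching_ss: SpliceSite, chrom: str, transcripts: Sequence[TranscriptModel]
) -> Optional[TranscriptModel]:
    """Pick the transcript interpreting the event.

    Candidates possess the matching splice site as an exon-intron boundary.
    Priority: MANE Select, then MANE Plus Clinical, then the largest
    transcript; residual ties go to the lexicographically earlier
    transcript ID.
    """
    candidates = []
    for tx in transcripts:
        if tx.chrom != chrom:
            continue
        sites = tx.donor_sites() if matching_ss.side == DONOR else tx.acceptor_sites()
        if matching_ss.pos in sites:
            candidates.append(tx)
    if not candidates:
        return None

    def rank(tx: TranscriptModel):
        return (
            0 if "MANE_Select" in tx.tags else 1 if "MANE_Plus_Clinical" in tx.tags else 2,
            -tx.length,
            tx.transcript_id,
        )

    return min(candidates, key=rank)


# ---------------------------------------------------------------------------
# Affected exon / hijacked splice site


def locate_affected_exon(
    novel_ss: int, side: str, transcript: TranscriptModel
) -> Optional[tuple[int, tuple[int, int], int]]:
    """(exon index, exon, hijacked exon-terminal coordinate) or None.

    For donor creation the affected exon is the one whose transcript-
    direction start is closest to, yet before, the novel site; its end is
    the hijacked splice site.  For acceptor creation, mirrored.
    """
    strand = transcript.strand
    best = None
    for i, (s, e) in enumerate(transcript.exons):
        if side == DONOR:
            if strand == "+":
                ok, dist, hijacked = s < novel_ss, novel_ss - s, e
            else:
                ok, dist, hijacked = e > novel_ss, e - novel_ss, s
        else:
            if strand == "+":
                ok, dist, hijacked = e > novel_ss, e - novel_ss, s
            else:
                ok, dist, hijacked = s < novel_ss, novel_ss - s, e
        if ok and (best is None or dist < best[0]):
            best = (dist, i, (s, e), hijacked)
    if best is None:
        return None
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# Depth track


class DepthTrack:
    """Per-base exonic read depth computed from aligned read blocks."""

    def __init__(self, reads: Sequence[ReadRecord] = ()):
        self._depth: dict[str, Counter] = defaultdict(Counter)
        for read in reads:
            for s, e in read.blocks:
                for pos in range(s, e + 1):
                    self._depth[read.chrom][pos] += 1

    def depth(self, chrom: str, pos: int) -> int:
        return self._depth[chrom][pos]

    def covered(self, chrom: str, start: int, end: int) -> bool:
        """True when every base of [start, end] has depth >= 1."""
        d = self._depth[chrom]
        return all(d[pos] > 0 for pos in range(start, end + 1))


# ---------------------------------------------------------------------------
# Classification


def _find_secondary_ss(
    side: str,
    strand: str,
    novel_ss: int,
    hijacked_edge: int,
    junctions: Sequence[SpliceJunction],
    chrom: str,
    window: int = 300,
) -> Optional[int]:
    """Secondary splice site of a cryptic exon, if a junction supports one.

    The qualifying junction has one edge on the hijacked splice site (intron
    side) and its other edge strictly between the hijacked site and the
    novel site, within ``window`` bp of the novel site, leaving at least one
    exonic base.  Several qualifying junctions: most unique reads, then
    nearest, then smaller coordinate.
    """
    # Which junction terminal must sit on the hijacked intron edge, and on
    # which side of the novel site the secondary edge must fall.
    donor_like = (side == DONOR and strand == "+") or (side == ACCEPTOR and strand == "-")
    candidates = []
    for j in junctions:
        if j.chrom != chrom or j.unique_reads < 1:
            continue
        if donor_like:
            # hijacked edge is an intron start; secondary edge = intron end
            if j.intron_start != hijacked_edge:
                continue
            secondary = j.intron_end
            dist = novel_ss - secondary
            if not (hijacked_edge < secondary <= novel_ss - 2):
                continue
        else:
            if j.intron_end != hijacked_edge:
                continue
            secondary = j.intron_start
            dist = secondary - novel_ss
            if not (novel_ss + 2 <= secondary < hijacked_edge):
                continue
        if 0 < dist <= window:
            candidates.append((-j.unique_reads, dist, secondary))
    if not candidates:
        return None
    return min(candidates)[2]


def classify(
    call: SSCVCall,
    transcript: TranscriptModel,
    sample_junctions: Sequence[SpliceJunction],
    depth_track: Optional[DepthTrack] = None,
    cryptic_window: int = 300,
) -> ConsequenceCall:
    """Classify the splicing consequence of one SSCV on one transcript."""
    v = call.variant
    side = v.side
    strand = transcript.strand
    novel_ss = v.pnj.primary_novel_ss.pos
    chrom = v.chrom

    located = locate_affected_exon(novel_ss, side, transcript)
    if located is None:
        return ConsequenceCall(category=AMBIGUOUS, reference_transcript_id=transcript.transcript_id)
    exon_idx, (es, ee), hijacked = located

    base = dict(
        reference_transcript_id=transcript.transcript_id,
        affected_exon_index=exon_idx,
        hijacked_ss=hijacked,
    )

    if es <= novel_ss <= ee:
        # the novel intron begins/ends inside the affected exon
        if side == DONOR:
            lost = (novel_ss, ee) if strand == "+" else (es, novel_ss)
        else:
            lost = (es, novel_ss) if strand == "+" else (novel_ss, ee)
        size = -(lost[1] - lost[0] + 1)
        return ConsequenceCall(
            category=PARTIAL_EXON_LOSS, changed_interval=lost, size_change=size, **base
        )

    # hijacked splice site expressed as its intron-terminal neighbour
    donor_like = (side == DONOR and strand == "+") or (side == ACCEPTOR and strand == "-")
    hijacked_edge = hijacked + 1 if donor_like else hijacked - 1

    secondary = _find_secondary_ss(
        side, strand, novel_ss, hijacked_edge, sample_junctions, chrom, cryptic_window
    )
    if secondary is not None:
        if donor_like:
            new_exon = (secondary + 1, novel_ss - 1)
        else:
            new_exon = (novel_ss + 1, secondary - 1)
        size = new_exon[1] - new_exon[0] + 1
        return ConsequenceCall(
            category=CRYPTIC_EXON, secondary_ss=secondary,
            changed_interval=new_exon, size_change=size, **base,
        )

    if depth_track is not None:
        lo, hi = min(hijacked, novel_ss), max(hijacked, novel_ss)
        if depth_track.covered(chrom, lo, hi):
            gained = (hijacked_edge, novel_ss - 1) if donor_like else (novel_ss + 1, hijacked_edge)
            size = gained[1] - gained[0] + 1
            return ConsequenceCall(
                category=EXON_EXTENSION, changed_interval=gained, size_change=size, **base
            )

    return ConsequenceCall(category=AMBIGUOUS, **base)


# ---------------------------------------------------------------------------
# Transcript reconstruction


def _ordered_exons(exons: Sequence[tuple[int, int]], strand: str):
    return list(exons) if strand == "+" else list(reversed(exons))


def _mrna_positions(exons: Sequence[tuple[int, int]], strand: str) -> list[int]:
    """Genomic position of every mature-transcript base, 5'->3'."""
    out = []
    for s, e in _ordered_exons(exons, strand):
        rng = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
        out.extend(rng)
    return out


def _build_mrna(genome: Genome, chrom: str, exons, strand: str) -> str:
    return "".join(
        genome.fetch(chrom, s, e, strand) for s, e in _ordered_exons(exons, strand)
    )


def _junction_offsets(exons, strand: str) -> list[int]:
    """Bases 5' of each exon-exon junction (one entry per junction)."""
    lengths = [e - s + 1 for s, e in _ordered_exons(exons, strand)]
    offsets = []
    total = 0
    for length in lengths[:-1]:
        total += length
        offsets.append(total)
    return offsets


def _alt_exons(conseq: ConsequenceCall, transcript: TranscriptModel) -> list[tuple[int, int]]:
    """Exon list of the altered transcript."""
    exons = list(transcript.exons)
    lo, hi = conseq.changed_interval
    if conseq.category == PARTIAL_EXON_LOSS:
        out = []
        for s, e in exons:
            if s <= lo and hi <= e:  # affected exon; trim the lost part
                if lo > s:
                    out.append((s, lo - 1))
                if hi < e:
                    out.append((hi + 1, e))
            else:
                out.append((s, e))
        return out
    if conseq.category == EXON_EXTENSION:
        out = []
        for s, e in exons:
            if e == lo - 1:  # exon immediately 5' (genomic) of the gained run
                out.append((s, hi))
            elif s == hi + 1:
                out.append((lo, e))
            else:
                out.append((s, e))
        return sorted(out)
    if conseq.category == CRYPTIC_EXON:
        return sorted(exons + [(lo, hi)])
    raise ValueError(f"cannot reconstruct category {conseq.category!r}")


def reconstruct_transcript(
    conseq: ConsequenceCall, transcript: TranscriptModel, genome: Genome
):
    """Reference and altered mature transcripts plus CDS bookkeeping.

    Returns (ref_mrna, alt_mrna, ref_cds, alt_cds, alt_junction_offsets,
    flags) where flags carries ``utr_only`` / ``start_skipped`` /
    ``stop_skipped`` / ``alt_cds_offset``; ref/alt CDS run from the start
    codon to the transcript 3' end (translation decides the stop).
    """
    chrom = transcript.chrom
    strand = transcript.strand
    ref_exons = list(transcript.exons)
    alt_exons = _alt_exons(conseq, transcript)
    ref_mrna = _build_mrna(genome, chrom, ref_exons, strand)
    alt_mrna = _build_mrna(genome, chrom, alt_exons, strand)
    flags = {"utr_only": False, "start_skipped": False, "stop_skipped": False,
             "alt_cds_offset": None, "ref_cds_offset": None}

    if not transcript.is_coding:
        return ref_mrna, alt_mrna, None, None, _junction_offsets(alt_exons, strand), flags

    lo, hi = conseq.changed_interval
    if hi < transcript.cds_start or lo > transcript.cds_end:
        flags["utr_only"] = True
        return ref_mrna, alt_mrna, None, None, _junction_offsets(alt_exons, strand), flags

    ref_pos = _mrna_positions(ref_exons, strand)
    alt_pos = _mrna_positions(alt_exons, strand)
    alt_index = {p: i for i, p in enumerate(alt_pos)}

    cds5_genomic = transcript.cds_start if strand == "+" else transcript.cds_end
    ref_off = ref_pos.index(cds5_genomic)
    if cds5_genomic not in alt_index:
        flags["start_skipped"] = True
        return ref_mrna, alt_mrna, None, None, _junction_offsets(alt_exons, strand), flags
    alt_off = alt_index[cds5_genomic]

    ref_cds = ref_mrna[ref_off:]
    # locate the original stop codon by translation and require it intact
    stop_idx = _first_stop(ref_cds)
    if stop_idx is not None:
        stop_genomic = ref_pos[ref_off + 3 * stop_idx : ref_off + 3 * stop_idx + 3]
        if any(p not in alt_index for p in stop_genomic):
            flags["stop_skipped"] = True
            return ref_mrna, alt_mrna, None, None, _junction_offsets(alt_exons, strand), flags

    alt_cds = alt_mrna[alt_off:]
    flags["ref_cds_offset"] = ref_off
    flags["alt_cds_offset"] = alt_off
    return ref_mrna, alt_mrna, ref_cds, alt_cds, _junction_offsets(alt_exons, strand), flags


# ---------------------------------------------------------------------------
# Protein prediction


def _first_stop(cds: str) -> Optional[int]:
    """Codon index of the first in-frame stop, or None."""
    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    idx = aa.find("*")
    return idx if idx >= 0 else None


def predict_protein_effect(
    ref_cds: str, alt_cds: str, size_change: int
) -> tuple[str, str, tuple[str, str]]:
    """(frame, ptc status, (ref protein, alt protein)).

    The homologous position of the original stop on the altered transcript
    is the reference stop offset shifted by the size change; a stop strictly
    before it is a PTC, a stop at (or beyond) it is non-PTC.
    """
    frame = "in_frame" if size_change % 3 == 0 else "frameshift"
    ref_stop = _first_stop(ref_cds)
    alt_stop = _first_stop(alt_cds)
    if ref_stop is None:
        return frame, "not_applicable", ("", "")
    homologous_nt = 3 * ref_stop + size_change
    if alt_stop is None:
        ptc = "non_ptc"
        alt_aa_len = (len(alt_cds) // 3)
    else:
        ptc = "ptc" if 3 * alt_stop < homologous_nt else "non_ptc"
        alt_aa_len = alt_stop
    ref_aa = str(Seq(ref_cds[: 3 * ref_stop]).translate())
    alt_aa = str(Seq(alt_cds[: 3 * alt_aa_len]).translate())
    return frame, ptc, (ref_aa, alt_aa)


def nmd_susceptibility(ptc_pos: int, last_junction_pos: Optional[int]) -> str:
    """The 50 bp rule on the altered mRNA.

    ``ptc_pos`` is the offset (bases 5' of) the stop codon; a PTC less than
    50 nt upstream of the last exon-exon junction, or downstream of it,
    escapes NMD.  Single-exon transcripts escape.
    """
    if last_junction_pos is None:
        return "escape"
    distance = last_junction_pos - ptc_pos
    return "escape" if distance < 50 else "susceptible"


def hgvs_protein_change(ref_aa: str, alt_aa: str, frameshift: bool = False) -> str:
    """Minimal HGVS-style description; novel residues rendered as X[n]."""
    ref = ref_aa.rstrip("*")
    alt = alt_aa.rstrip("*")
    if ref == alt:
        return "p.(=)"
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    if frameshift:
        anchor = ref[p] if p < len(ref) else "*"
        return f"{anchor}{p + 1}fs"
    s = 0
    while s < min(len(ref), len(alt)) - p and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]:
        s += 1
    deleted = ref[p : len(ref) - s]
    inserted = alt[p : len(alt) - s]
    ins_repr = f"X[{len(inserted)}]"
    if inserted and not deleted:
        if p == 0:
            return f"{ref[0]}1ins{ins_repr}"
        left, right = ref[p - 1], ref[p] if p < len(ref) else "*"
        return f"{left}{p}_{right}{p + 1}ins{ins_repr}"
    first = f"{deleted[0]}{p + 1}"
    last = f"{deleted[-1]}{p + len(deleted)}"
    span = first if len(deleted) == 1 else f"{first}_{last}"
    if deleted and not inserted:
        return f"{span}del"
    return f"{span}delins{ins_repr}"


# ---------------------------------------------------------------------------
# End-to-end classification of one call


def classify_consequence(
    call: SSCVCall,
    transcripts: Sequence[TranscriptModel],
    sample_junctions: Sequence[SpliceJunction],
    reads_or_depth: Optional[Sequence[ReadRecord] | DepthTrack] = None,
    genome: Optional[Genome] = None,
    cryptic_window: int = 300,
) -> ConsequenceCall:
    """Full classification: reference transcript, category, frame/PTC/NMD, HGVS."""
    matching = call.variant.pnj.matching_ss
    transcript = select_reference_transcript(matching, call.chrom, transcripts)
    if transcript is None:
        return ConsequenceCall(category=AMBIGUOUS)
    depth = (
        reads_or_depth
        if isinstance(reads_or_depth, DepthTrack)
        else DepthTrack(reads_or_depth or ())
    )
    conseq = classify(call, transcript, sample_junctions, depth, cryptic_window)
    if conseq.category == AMBIGUOUS or genome is None:
        return conseq
    if not transcript.is_coding:
        return conseq

    _, alt_mrna, ref_cds, alt_cds, junctions, flags = reconstruct_transcript(
        conseq, transcript, genome
    )
    if flags["utr_only"]:
        return dataclasses.replace(conseq, utr_only=True)
    if flags["start_skipped"] or flags["stop_skipped"] or ref_cds is None:
        return conseq

    frame, ptc, (ref_aa, alt_aa) = predict_protein_effect(ref_cds, alt_cds, conseq.size_change)
    nmd = "not_applicable"
    hgvs = None
    if ptc != "not_applicable":
        hgvs = hgvs_protein_change(ref_aa, alt_aa, frameshift=(frame == "frameshift"))
    if ptc == "ptc":
        alt_stop = _first_stop(alt_cds)
        ptc_pos = flags["alt_cds_offset"] + 3 * alt_stop  # bases 5' of the stop codon
        last_junction = junctions[-1] if junctions else None
        nmd = nmd_susceptibility(ptc_pos, last_junction)
    return dataclasses.replace(conseq, frame=frame, ptc=ptc, nmd=nmd, hgvs_p=hgvs)
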