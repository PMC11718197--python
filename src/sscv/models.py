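"""Core genomic data model and coordinate conventions.

Every coordinate in this package is 1-based and inclusive, matching the two
dominant input formats (STAR ``SJ.out.tab`` and GTF).  A splice site is
represented by the genomic coordinate of the intron-terminal base: the donor
site is the first base of the intron and the acceptor site is the last base
of the intron, both in transcript direction.  On the plus strand the donor is
therefore ``intron_start`` and the acceptor ``intron_end``; on the minus
strand the roles swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

DONOR = "donor"
ACCEPTOR = "acceptor"

_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class Genome:
    """A reference genome held as uppercase in-memory sequences.

    ``fetch`` is the single strand-aware accessor used everywhere; motif code
    never hand-rolls reverse complements.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains non-nucleotide characters: {sorted(bad)}"
                )
            if name in self.sequences:
                raise ValueError(f"duplicate sequence name {name!r}")
            self.sequences[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of [start, end] (1-based inclusive).

        On the minus strand the reverse complement is returned.
        """
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"window {chrom}:{start}-{end} outside contig (length {len(seq)})"
            )
        sub = seq[start - 1 : end]
        if strand == "-":
            return reverse_complement(sub)
        return sub

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos, "+")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with exons in genomic order (1-based inclusive)."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    tags: frozenset[str] = frozenset()
    biotype: str = ""

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {(s1, e1)} / {(s2, e2)}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals (first base, last base)."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def donor_sites(self) -> list[int]:
        """First intron base of each intron, in transcript direction."""
        ivs = self.introns()
        return [s for s, _ in ivs] if self.strand == "+" else [e for _, e in ivs]

    def acceptor_sites(self) -> list[int]:
        ivs = self.introns()
        return [e for _, e in ivs] if self.strand == "+" else [s for s, _ in ivs]


@dataclass(frozen=True)
class SpliceJunction:
    """One intron observed in one sample.

    ``intron_start``/``intron_end`` are the first and last intronic bases.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str  # '+', '-' or 'undetermined'
    unique_reads: int = 0

    def __post_init__(self):
        if self.intron_start > self.intron_end:
            raise ValueError("intron_start must be <= intron_end")
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be >= 0")

    @property
    def key(self) -> tuple[str, int, int]:
        """Panel/identity key: strand is stored but not part of the key."""
        return (self.chrom, self.intron_start, self.intron_end)

    def overlaps(self, other: "SpliceJunction") -> bool:
        return (
            self.chrom == other.chrom
            and self.intron_start <= other.intron_end
            and other.intron_start <= self.intron_end
        )


@dataclass(frozen=True)
class ReadRecord:
    """A spliced, aligned read (stands in for one BAM record).

    ``blocks`` are the aligned reference segments (1-based inclusive) in
    order; gaps between consecutive blocks are spliced-out introns.  The
    stored sequence is on the reference plus strand, SAM-style.
    """

    read_id: str
    sequence: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    mapping_quality: int = 60
    base_qualities: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        blocks = tuple(tuple(b) for b in self.blocks)
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 <= e1:
                raise ValueError("read blocks must be sorted and non-overlapping")
        qlen = sum(e - s + 1 for s, e in blocks)
        if qlen != len(self.sequence):
            raise ValueError("sequence length must equal total block length")
        object.__setattr__(self, "blocks", blocks)

    @property
    def span(self) -> tuple[int, int]:
        """Reference envelope including spliced gaps."""
        return (self.blocks[0][0], self.blocks[-1][1])

    def base_at(self, pos: int) -> Optional[tuple[str, int]]:
        """(base, base quality) at reference position, None if spliced out."""
        off = 0
        for s, e in self.blocks:
            if s <= pos <= e:
                i = off + (pos - s)
                q = self.base_qualities[i] if self.base_qualities else 40
                return self.sequence[i], q
            off += e - s + 1
        return None

    def covers(self, pos: int) -> bool:
        """True if the reference envelope (introns included) spans pos."""
        s, e = self.span
        return s <= pos <= e


@dataclass(frozen=True)
class RepeatElement:
    """A RepeatMasker element, coordinates already converted to 1-based."""

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    rep_class: str
    rep_family: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("repeat end must be >= start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class AFTable:
    """Population allele-frequency lookup; absent keys have frequency 0."""

    def __init__(self, entries: Mapping[tuple[str, int, str, str], float] = ()):
        self._af: dict[tuple[str, int, str, str], float] = {}
        for key, af in dict(entries).items():
            self.add(*key, af)

    def add(self, chrom: str, pos: int, ref: str, alt: str, af: float) -> None:
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0, 1]")
        self._af[(chrom, int(pos), ref, alt)] = af

    def get(self, chrom: str, pos: int, ref: str, alt: str) -> float:
        return self._af.get((chrom, int(pos), ref, alt), 0.0)

    def __len__(self) -> int:
        return len(self._af)

    def items(self):
        return self._af.items()


@dataclass(frozen=True)
class SpliceSite:
    """A splice site: intron-terminal genomic coordinate plus its side."""

    pos: int
    side: str  # DONOR or ACCEPTOR

    def __post_init__(self):
        if self.side not in (DONOR, ACCEPTOR):
            raise ValueError(f"invalid side {self.side!r}")


@dataclass(frozen=True)
class PrimaryNovelJunction:
    """A junction with one annotated edge and one unannotated edge.

    ``junction`` is the position-adjusted junction (the matching edge shifted
    onto the exact annotated boundary, the novel edge shifted by the same
    offset).  ``source`` keeps the raw observed record.
    """

    junction: SpliceJunction
    source: SpliceJunction
    matching_ss: SpliceSite  # annotated side
    primary_novel_ss: SpliceSite  # novel side; complementary to matching
    matched_transcripts: tuple[str, ...]
    strand: str  # resolved from the matched transcripts
    adjustment_offset: int = 0

    @property
    def matching_edge_is_start(self) -> bool:
        return self.matching_ss.pos == self.junction.intron_start

    @property
    def unique_reads(self) -> int:
        return self.source.unique_reads


@dataclass(frozen=True)
class CandidateVariant:
    """A substitution that would create/improve the novel splice motif."""

    chrom: str
    pos: int
    ref_base: str  # genome plus strand
    alt_base: str  # genome plus strand
    side: str  # which motif it creates: DONOR or ACCEPTOR
    relative_position: int  # signed, transcript direction, 0 excluded
    pnj: PrimaryNovelJunction
    mismatch_reads: int = 0
    realign_support: int = 0
    population_af: float = 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class MiniTranscript:
    """A short template used for realignment-based validation.

    Junction-spanning kinds are 20-mers (10 bases per edge); the intron
    retention kind is a 21-mer centred on the variant.  Sequences are on the
    genome plus strand so that they align directly against stored read
    sequences.  ``sscv_offset`` is the 0-based offset of the variant base
    within ``sequence`` when the window covers it, else None.
    """

    kind: str  # 'primary_novel' | 'reference' | 'intron_retention'
    with_sscv: bool
    sequence: str
    sscv_offset: Optional[int] = None
    ref_transcript_length: int = 0  # tie-break among multiple reference minis


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    best_kind: Optional[str]  # e.g. 'reference' or None when unaligned
    with_sscv: Optional[bool]
    edit_distance: Optional[int]


@dataclass(frozen=True)
class SSCVCall:
    """A validated splice-site creating variant with its evidence."""

    sample_id: str
    variant: CandidateVariant
    population_af: float = 0.0
    panelled: bool = False
    af_filtered: bool = False
    passed: bool = True

    @property
    def chrom(self) -> str:
        return self.variant.chrom

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key


@dataclass(frozen=True)
class ConsequenceCall:
    """Splicing-consequence classification for one SSCV."""

    category: str  # partial_exon_loss | exon_extension | cryptic_exon | ambiguous
    reference_transcript_id: Optional[str] = None
    affected_exon_index: Optional[int] = None  # 0-based, genomic order
    hijacked_ss: Optional[int] = None  # exon-terminal coordinate
    secondary_ss: Optional[int] = None  # intron-terminal; cryptic exon only
    changed_interval: Optional[tuple[int, int]] = None  # lost/gained genomic bases
    size_change: int = 0  # signed bp on the mature transcript
    frame: str = "not_applicable"  # in_frame | frameshift | not_applicable
    ptc: str = "not_applicable"  # ptc | non_ptc | not_applicable
    nmd: str = "not_applicable"  # susceptible | escape | not_applicable
    hgvs_p: Optional[str] = None
    utr_only: bool = False


@dataclass(frozen=True)
class AluHit:
    """An SSCV placed inside an Alu element, with reference-Alu coordinates."""

    call: SSCVCall
    element: RepeatElement
    family: str  # AluJ | AluS | AluY | other
    orientation: Optional[str]  # sense | antisense | None if strand unknown
    low_identity: bool = False
    alu_pos_variant: Optional[int] = None
    alu_pos_primary_ss: Optional[int] = None
    alu_pos_secondary_ss: Optional[int] = None
    alu_exon_start: Optional[int] = None  # cryptic exons: consensus coords
    alu_exon_end: Optional[int] = None
    consequence: Optional[ConsequenceCall] = None


@dataclass(frozen=True)
class AluCluster:
    alu_position: int
    count: int
    side: str
    orientation: str
    family_counts: tuple[tuple[str, int], ...] = ()


def alu_family(rep_name: str) -> str:
    prefix = rep_name[:4]
    return prefix if prefix in ("AluJ", "AluS", "AluY") else "other"
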