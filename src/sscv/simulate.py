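"""Deterministic synthetic fixtures with planted splice-site creating variants.

The simulator builds a miniature genome of multi-exon protein-coding genes
(canonical GT..AG introns, ATG..stop CDS, one MANE Select transcript per
gene), plants SSCV scenarios of chosen splicing category with analytically
known consequences, and emits per-sample junction tables, spliced reads and
an allele-frequency table.  Everything is driven by one integer seed and
regenerates byte-identically.

The generative read model captures the features the detector relies on —
junction-spanning reads, heterozygous variant alleles with configurable
splicing penetrance, occasional intron-retaining (pre-mRNA) molecules that
expose intronic variant bases, and uniform substitution sequencing errors —
and nothing else (no GC bias, no fragment-length model, no indels).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from sscv.models import (
    ACCEPTOR,
    DONOR,
    AFTable,
    Genome,
    ReadRecord,
    RepeatElement,
    SpliceJunction,
    TranscriptModel,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))
_NO_T = np.array(list("ACG"))  # stop codons all start with T

# consensus windows written at planted sites, transcript orientation
_DONOR_CONSENSUS = {-2: "A", -1: "G", 1: "G", 2: "T", 3: "A", 4: "A", 5: "G", 6: "T"}
_ACCEPTOR_CONSENSUS = {-6: "T", -5: "C", -4: "A", -3: "C", -2: "A", -1: "G", 1: "G"}

from sscv.discovery import MOTIF_RULES  # allowed base sets per relative position


@dataclass
class Scenario:
    """One SSCV to plant.

    ``side`` is the motif being created; ``relative_position`` the variant
    position in the motif (transcript direction); ``category_target`` the
    splicing consequence the geometry should produce.  ``event_size`` is the
    number of exonic bases lost (partial exon loss), gained (extension) or
    the cryptic exon length.  ``force_ptc`` plants an in-frame stop inside
    the gained/cryptic interval.
    """

    side: str = DONOR
    relative_position: int = -1
    category_target: str = "exon_extension"
    event_size: int = 60
    penetrance: float = 0.5
    allele_frequency: float = 0.0001
    force_ptc: bool = False
    in_alu: bool = False


@dataclass
class FixtureTruth:
    """Ground truth for one planted SSCV (all coordinates genomic, 1-based)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    side: str
    relative_position: int
    pos: int
    ref: str  # genome plus strand
    alt: str
    novel_ss: int
    matching_ss: int
    hijacked_ss: int  # exon-terminal coordinate
    secondary_ss: Optional[int]
    novel_junction: tuple[int, int]  # intron first/last base
    hijacked_junction: tuple[int, int]
    secondary_junction: Optional[tuple[int, int]]
    category: str
    size_change: int
    frame: str
    ptc: str
    nmd: str
    alt_exons: tuple[tuple[int, int], ...]
    penetrance: float
    allele_frequency: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class _Gene:
    gene_id: str
    transcript_id: str
    strand: str
    offset: int  # genomic start of the gene region (1-based)
    premrna: list  # mutable list of transcript-orientation bases
    exons_gs: list  # gene-space exon intervals, 1-based inclusive
    cds_start_gs: int  # first CDS base, gene-space
    cds_len: int  # including stop codon

    @property
    def length(self) -> int:
        return len(self.premrna)

    def g(self, p: int) -> int:
        """Gene-space (transcript orientation) -> genomic coordinate."""
        if self.strand == "+":
            return self.offset + p - 1
        return self.offset + self.length - p

    def interval_g(self, a: int, b: int) -> tuple[int, int]:
        x, y = self.g(a), self.g(b)
        return (x, y) if x <= y else (y, x)

    def introns_gs(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons_gs, self.exons_gs[1:])
        ]


def synthetic_alu_consensus(seed: int = 7, arm: int = 130, insert: int = 31) -> str:
    """A synthetic dimeric Alu-like consensus (clearly labelled synthetic).

    Two near-identical arms separated by an A-rich linker, the right arm
    carrying an extra internal segment, ending in a short poly-A tail —
    the structural features needed to exercise arm-to-arm coordinate
    mapping.  This is NOT the published Alu consensus.
    """
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(_BASES, size=arm))
    extra = "".join(rng.choice(_BASES, size=insert))
    right = left[:40] + extra + left[40:]
    return left + "AAAAA" + right + "A" * 15


class SpliceSimulator:
    """Build a reference, plant SSCVs, and emit per-sample sequencing data."""

    def __init__(
        self,
        seed: int = 1,
        n_genes: int = 4,
        n_exons: tuple[int, int] = (3, 5),
        exon_len: tuple[int, int] = (120, 180),
        intron_len: tuple[int, int] = (550, 750),
        chrom: str = "chrS",
        intergenic: int = 400,
        alternate_strands: bool = True,
    ):
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.chrom = chrom
        self.genes: list[_Gene] = []
        self.truths: list[FixtureTruth] = []
        self.repeats: list[RepeatElement] = []
        self.alu_consensus = synthetic_alu_consensus()
        self._finalized = False
        offset = intergenic
        for i in range(n_genes):
            strand = "+" if (not alternate_strands or i % 2 == 0) else "-"
            gene = self._make_gene(f"G{i+1}", f"TX{i+1:04d}", strand, offset, n_exons, exon_len, intron_len)
            self.genes.append(gene)
            offset += gene.length + intergenic

    # -- reference construction ------------------------------------------

    def _make_gene(self, gene_id, tx_id, strand, offset, n_exons, exon_len, intron_len) -> _Gene:
        rng = self.rng
        k = int(rng.integers(n_exons[0], n_exons[1] + 1))
        exon_lens = [int(rng.integers(exon_len[0], exon_len[1] + 1)) for _ in range(k)]
        intron_lens = [int(rng.integers(intron_len[0], intron_len[1] + 1)) for _ in range(k - 1)]
        exons_gs = []
        pos = 1
        pieces = []
        for i, el in enumerate(exon_lens):
            exons_gs.append((pos, pos + el - 1))
            pieces.append("".join(rng.choice(_BASES, size=el)))
            pos += el
            if i < k - 1:
                il = intron_lens[i]
                intron = "GT" + "".join(rng.choice(_BASES, size=il - 4)) + "AG"
                pieces.append(intron)
                pos += il
        premrna = list("".join(pieces))
        # CDS: starts 60 nt into the transcript, stop codon placed in the
        # last exon leaving a 3' UTR
        tx_len = sum(exon_lens)
        utr5 = 60
        last_exon_start_tx = tx_len - exon_lens[-1]
        stop_end_tx = last_exon_start_tx + max(30, exon_lens[-1] - 90)
        cds_len = stop_end_tx - utr5
        cds_len -= cds_len % 3
        # write CDS content in transcript (exonic) space
        exonic_positions = []
        for a, b in exons_gs:
            exonic_positions.extend(range(a, b + 1))
        cds_positions = exonic_positions[utr5 : utr5 + cds_len]
        codons = self._stop_free_codons(cds_len // 3 - 2)
        cds_seq = "ATG" + codons + "TAA"
        for p, base in zip(cds_positions, cds_seq):
            premrna[p - 1] = base
        # keep the rest of the CDS-frame clean: remove accidental in-frame
        # stops introduced by intron boundaries? CDS is purely exonic, so
        # the written sequence fully determines the frame.
        return _Gene(gene_id, tx_id, strand, offset, premrna, exons_gs, cds_positions[0], cds_len)

    def _stop_free_codons(self, n: int) -> str:
        rng = self.rng
        out = []
        stops = {"TAA", "TAG", "TGA"}
        while len(out) < n:
            codon = "".join(rng.choice(_BASES, size=3))
            if codon not in stops:
                out.append(codon)
        return "".join(out)

    # -- planting ---------------------------------------------------------

    def plant(self, scenario: Scenario, gene_index: Optional[int] = None) -> FixtureTruth:
        if self._finalized:
            raise RuntimeError("cannot plant after the reference is finalized")
        if gene_index is None:
            gene_index = len(self.truths)
        gene = self.genes[gene_index]
        introns = gene.introns_gs()
        if len(introns) < 2:
            raise ValueError("gene too small for planting")
        # choose the intron so the affected exon is internal: for donor
        # creation the affected exon precedes the intron, for acceptor
        # creation it follows it (and must not be the stop-carrying last exon)
        if scenario.side == DONOR:
            ki = 1
        else:
            ki = 0 if len(introns) == 2 else 1
        is_, ie_ = introns[ki]
        S = scenario.event_size
        side = scenario.side

        if scenario.category_target == "partial_exon_loss":
            if side == DONOR:
                novel_gs = is_ - S
                novel_intron_gs = (novel_gs, ie_)
            else:
                novel_gs = ie_ + S
                novel_intron_gs = (is_, novel_gs)
            cryptic_gs = None
        elif scenario.category_target in ("exon_extension", "ambiguous"):
            # "ambiguous" uses extension geometry; the sampler then leaves a
            # coverage hole in the gained run so no category can be assigned
            cryptic_gs = None
            if side == DONOR:
                novel_gs = is_ + S
                novel_intron_gs = (novel_gs, ie_)
                # keep the original GT donor; fill the rest of the gained run
                self._fill_no_stop(gene, is_ + 2, novel_gs - 1)
                gene.premrna[is_ + 1] = "C"  # neutralize the T of GT as a codon start
            else:
                novel_gs = ie_ - S
                novel_intron_gs = (is_, novel_gs)
                # keep the original AG acceptor at the intron end
                self._fill_no_stop(gene, novel_gs + 1, ie_ - 2)
        elif scenario.category_target == "cryptic_exon":
            ce1 = is_ + 120
            ce2 = ce1 + S - 1
            if scenario.in_alu:
                self._plant_alu(gene, (ce1, ce2))
            self._fill_no_stop(gene, ce1, ce2)
            if side == DONOR:
                novel_gs = ce2 + 1
                novel_intron_gs = (novel_gs, ie_)
                cryptic_secondary_gs = ce1 - 1  # acceptor
                # consensus acceptor motif at the secondary site
                for rel, base in _ACCEPTOR_CONSENSUS.items():
                    p = cryptic_secondary_gs + rel + 1 if rel < 0 else cryptic_secondary_gs + 1
                    gene.premrna[p - 1] = base
            else:
                novel_gs = ce1 - 1
                novel_intron_gs = (is_, novel_gs)
                cryptic_secondary_gs = ce2 + 1  # donor
                for rel, base in _DONOR_CONSENSUS.items():
                    p = cryptic_secondary_gs + rel - 1 if rel > 0 else cryptic_secondary_gs + rel
                    gene.premrna[p - 1] = base
            cryptic_gs = (ce1, ce2)
        else:
            raise ValueError(f"unknown category target {scenario.category_target!r}")

        # write the essential bases of the motif-to-be: the spliceosomal
        # dinucleotide (post-mutation) and a disallowed reference base at the
        # variant position.  Stop-inert bases are preferred so no premature
        # stop is written into the reference CDS; a repair pass below keeps
        # the reference reading frame clean regardless.
        consensus = _DONOR_CONSENSUS if side == DONOR else _ACCEPTOR_CONSENSUS
        allowed, required = MOTIF_RULES[side]
        rel = scenario.relative_position
        if rel not in consensus:
            raise ValueError(f"relative position {rel} outside the {side} window")

        def gs_of(r: int) -> int:
            if side == DONOR:
                return novel_gs + r - 1 if r > 0 else novel_gs + r
            return novel_gs + r + 1 if r < 0 else novel_gs + r

        protected = {gs_of(rel)}
        for r, base in required:
            if r != rel:
                gene.premrna[gs_of(r) - 1] = base
                protected.add(gs_of(r))
        alt_t = consensus[rel]
        ref_t = next(c for c in "CATG" if c not in allowed[rel] and c != alt_t)
        gene.premrna[gs_of(rel) - 1] = ref_t

        if scenario.force_ptc:
            self._plant_inframe_stop(gene, scenario, novel_intron_gs, cryptic_gs, is_, ie_)
        self._repair_ref_stops(gene, protected)

        truth = self._compute_truth(gene, scenario, ki, novel_gs, novel_intron_gs, cryptic_gs, ref_t, alt_t)
        self.truths.append(truth)
        return truth

    def _fill_no_stop(self, gene: _Gene, a: int, b: int) -> None:
        """Rewrite [a, b] without T, so no stop codon can start inside it."""
        if b < a:
            return
        seq = self.rng.choice(_NO_T, size=b - a + 1)
        gene.premrna[a - 1 : b] = list(seq)

    def _exonic_positions(self, gene: _Gene) -> list[int]:
        out = []
        for a, b in gene.exons_gs:
            out.extend(range(a, b + 1))
        return out

    def _repair_ref_stops(self, gene: _Gene, protected: set[int]) -> None:
        """Ensure the reference CDS has no stop before its terminal one.

        Motif edits written into coding exons can accidentally create an
        in-frame stop; any such codon gets one of its unconstrained bases
        set to C (no stop codon contains C).
        """
        exonic = self._exonic_positions(gene)
        start_idx = exonic.index(gene.cds_start_gs)
        cds_positions = exonic[start_idx : start_idx + gene.cds_len]
        for _ in range(30):
            cds = "".join(gene.premrna[p - 1] for p in cds_positions)
            stop = self._first_stop(cds)
            if stop is not None and 3 * stop == gene.cds_len - 3:
                return
            if stop is None:
                raise RuntimeError("terminal stop codon of the reference CDS was destroyed")
            codon_positions = cds_positions[3 * stop : 3 * stop + 3]
            free = [p for p in codon_positions if p not in protected]
            if not free:
                raise RuntimeError("cannot repair premature stop: all bases constrained")
            gene.premrna[free[0] - 1] = "C"
        raise RuntimeError("reference stop repair did not converge")

    def _plant_inframe_stop(self, gene, scenario, novel_intron_gs, cryptic_gs, is_, ie_):
        """Insert TAA in the reading frame inside the gained/cryptic bases."""
        if scenario.category_target == "cryptic_exon":
            region = cryptic_gs
        elif scenario.side == DONOR:
            region = (is_, novel_intron_gs[0] - 1)
        else:
            region = (novel_intron_gs[1] + 1, ie_)
        alt_exons = self._alt_exons_gs(gene, scenario, novel_intron_gs, cryptic_gs)
        exonic = []
        for a, b in alt_exons:
            exonic.extend(range(a, b + 1))
        cds_offset = exonic.index(gene.cds_start_gs)
        start_idx = exonic.index(region[0])
        phase = (start_idx - cds_offset) % 3
        shift = (3 - phase) % 3
        p = region[0] + shift + 6  # safely inside the region
        gene.premrna[p - 1 : p + 2] = list("TAA")

    def _plant_alu(self, gene: _Gene, cryptic_gs: tuple[int, int]) -> None:
        """Embed an antisense copy of the synthetic Alu consensus around the exon."""
        consensus = self.alu_consensus
        a1 = cryptic_gs[0] - 60
        a2 = a1 + len(consensus) - 1
        copy = list(reverse_complement(consensus))
        # a few substitutions so the copy is a realistic, non-identical instance
        for _ in range(8):
            i = int(self.rng.integers(0, len(copy)))
            copy[i] = str(self.rng.choice(_BASES))
        gene.premrna[a1 - 1 : a2] = copy
        g1, g2 = gene.interval_g(a1, a2)
        elem_strand = "-" if gene.strand == "+" else "+"
        self.repeats.append(
            RepeatElement(
                chrom=self.chrom, start=g1, end=g2, strand=elem_strand,
                rep_name="AluSyn1", rep_class="SINE", rep_family="Alu",
            )
        )

    # -- truth ------------------------------------------------------------

    def _alt_exons_gs(self, gene, scenario, novel_intron_gs, cryptic_gs):
        """Exon intervals of the altered transcript, gene-space."""
        ns, ne = novel_intron_gs
        # exonic bases inside the novel intron are removed; intronic bases
        # outside it (gained run, cryptic exon) become exonic
        exonic = set()
        for a, b in gene.exons_gs:
            exonic.update(range(a, b + 1))
        if cryptic_gs is not None:
            exonic.update(range(cryptic_gs[0], cryptic_gs[1] + 1))
        if scenario.category_target in ("exon_extension", "ambiguous"):
            introns = gene.introns_gs()
            # gained interval: intron bases outside the novel intron
            for a, b in introns:
                if ns <= a <= ne or ns <= b <= ne:
                    for p in range(a, b + 1):
                        if not ns <= p <= ne:
                            exonic.add(p)
        exonic -= set(range(ns, ne + 1))
        # collapse to intervals
        merged = []
        for p in sorted(exonic):
            if merged and merged[-1][1] == p - 1:
                merged[-1][1] = p
            else:
                merged.append([p, p])
        return [(a, b) for a, b in merged]

    def _compute_truth(self, gene, scenario, ki, novel_gs, novel_intron_gs, cryptic_gs, ref_t, alt_t):
        is_, ie_ = gene.introns_gs()[ki]
        side = scenario.side
        alt_exons_gs = self._alt_exons_gs(gene, scenario, novel_intron_gs, cryptic_gs)
        ref_len = sum(b - a + 1 for a, b in gene.exons_gs)
        alt_len = sum(b - a + 1 for a, b in alt_exons_gs)
        size_change = alt_len - ref_len
        frame = "in_frame" if size_change % 3 == 0 else "frameshift"
        ambiguous = scenario.category_target == "ambiguous"

        def mrna(exons):
            return "".join("".join(gene.premrna[a - 1 : b]) for a, b in exons)

        def cds_offset(exons):
            off = 0
            for a, b in exons:
                if a <= gene.cds_start_gs <= b:
                    return off + gene.cds_start_gs - a
                off += b - a + 1
            return None

        ref_mrna = mrna(gene.exons_gs)
        alt_mrna = mrna(alt_exons_gs)
        r_off = cds_offset(gene.exons_gs)
        a_off = cds_offset(alt_exons_gs)
        ptc = nmd = "not_applicable"
        if ambiguous:
            size_change = 0
            frame = "not_applicable"
            a_off = None
        if a_off is not None:
            ref_stop = self._first_stop(ref_mrna[r_off:])
            alt_stop = self._first_stop(alt_mrna[a_off:])
            homologous = 3 * ref_stop + size_change
            if alt_stop is None:
                ptc = "non_ptc"
            elif 3 * alt_stop < homologous:
                ptc = "ptc"
            else:
                ptc = "non_ptc"
            if ptc == "ptc":
                lengths = [b - a + 1 for a, b in alt_exons_gs]
                last_junction = sum(lengths[:-1]) if len(lengths) > 1 else None
                ptc_pos = a_off + 3 * alt_stop
                if last_junction is None or last_junction - ptc_pos < 50:
                    nmd = "escape"
                else:
                    nmd = "susceptible"

        # genomic conversions
        novel_junction = gene.interval_g(*novel_intron_gs)
        hijacked_junction = gene.interval_g(is_, ie_)
        rel = scenario.relative_position
        if side == DONOR:
            var_gs = novel_gs + rel - 1 if rel > 0 else novel_gs + rel
            matching_gs = ie_
            if scenario.category_target == "partial_exon_loss":
                hijacked_gs = is_ - 1  # unchanged original donor exon end
            else:
                hijacked_gs = is_ - 1
        else:
            var_gs = novel_gs + rel + 1 if rel < 0 else novel_gs + rel
            matching_gs = is_
            hijacked_gs = ie_ + 1
        secondary_gs = None
        secondary_junction = None
        if cryptic_gs is not None:
            if side == DONOR:
                secondary_gs = cryptic_gs[0] - 1
                secondary_junction = gene.interval_g(is_, secondary_gs)
            else:
                secondary_gs = cryptic_gs[1] + 1
                secondary_junction = gene.interval_g(secondary_gs, ie_)

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if gene.strand == "+":
            ref_g, alt_g = ref_t, alt_t
        else:
            ref_g, alt_g = comp[ref_t], comp[alt_t]

        return FixtureTruth(
            gene_id=gene.gene_id,
            transcript_id=gene.transcript_id,
            chrom=self.chrom,
            strand=gene.strand,
            side=side,
            relative_position=rel,
            pos=gene.g(var_gs),
            ref=ref_g,
            alt=alt_g,
            novel_ss=gene.g(novel_gs),
            matching_ss=gene.g(matching_gs),
            hijacked_ss=gene.g(hijacked_gs),
            secondary_ss=gene.g(secondary_gs) if secondary_gs else None,
            novel_junction=novel_junction,
            hijacked_junction=hijacked_junction,
            secondary_junction=secondary_junction,
            category=scenario.category_target,
            size_change=size_change,
            frame=frame,
            ptc=ptc,
            nmd=nmd,
            alt_exons=tuple(gene.interval_g(a, b) for a, b in alt_exons_gs),
            penetrance=scenario.penetrance,
            allele_frequency=scenario.allele_frequency,
        )

    @staticmethod
    def _first_stop(cds: str) -> Optional[int]:
        aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        idx = aa.find("*")
        return idx if idx >= 0 else None

    # -- finalized reference ---------------------------------------------

    def genome(self) -> Genome:
        self._finalized = True
        total = max(g.offset + g.length for g in self.genes) + 400
        seq = list(np.random.default_rng(self.seed + 10_000).choice(_BASES, size=total))
        for gene in self.genes:
            block = "".join(gene.premrna)
            if gene.strand == "-":
                block = reverse_complement(block)
            seq[gene.offset - 1 : gene.offset - 1 + gene.length] = list(block)
        return Genome({self.chrom: "".join(seq)})

    def transcripts(self) -> list[TranscriptModel]:
        out = []
        for gene in self.genes:
            exons = sorted(gene.interval_g(a, b) for a, b in gene.exons_gs)
            cds_g = [gene.g(gene.cds_start_gs), gene.g(self._cds_end_gs(gene))]
            out.append(
                TranscriptModel(
                    transcript_id=gene.transcript_id,
                    gene_id=gene.gene_id,
                    gene_name=gene.gene_id,
                    chrom=self.chrom,
                    strand=gene.strand,
                    exons=tuple(exons),
                    cds_start=min(cds_g),
                    cds_end=max(cds_g),
                    tags=frozenset({"MANE_Select", "basic"}),
                    biotype="protein_coding",
                )
            )
        return out

    def _cds_end_gs(self, gene: _Gene) -> int:
        exonic = []
        for a, b in gene.exons_gs:
            exonic.extend(range(a, b + 1))
        start_idx = exonic.index(gene.cds_start_gs)
        return exonic[start_idx + gene.cds_len - 1]

    def af_table(self) -> AFTable:
        table = AFTable()
        for t in self.truths:
            table.add(t.chrom, t.pos, t.ref, t.alt, t.allele_frequency)
        return table

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for tx in self.transcripts():
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_name "{tx.gene_name}"; transcript_type "{tx.biotype}"; '
                    + " ".join(f'tag "{t}";' for t in sorted(tx.tags))
                )
                fh.write(
                    f"{tx.chrom}\tsim\ttranscript\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
                for s, e in tx.exons:
                    fh.write(f"{tx.chrom}\tsim\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n")
                if tx.is_coding:
                    for s, e in tx.exons:
                        cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                        if cs <= ce:
                            fh.write(
                                f"{tx.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{tx.strand}\t.\t{attrs}\n"
                            )

    # -- sampling ---------------------------------------------------------

    def sample(
        self,
        sample_id: str,
        carrier: dict[int, bool] | bool = True,
        read_length: int = 100,
        depth: int = 60,
        error_rate: float = 0.0,
        seed: Optional[int] = None,
        ir_fraction: float = 0.12,
        min_overhang: int = 8,
    ) -> "SimulatedSample":
        """Generate one sample's reads and junction table.

        ``carrier`` marks which planted variants this individual carries
        (heterozygous); ``depth`` is the number of reads drawn per locus
        window.  Junction rows are tallied from the generated reads with a
        STAR-like minimum overhang.
        """
        if seed is None:
            seed = zlib.crc32(sample_id.encode()) % 65_536
        rng = np.random.default_rng(self.seed * 100_003 + seed)
        genome = self.genome()
        chrom_seq = genome.sequences[self.chrom]
        reads: list[ReadRecord] = []
        for t_idx, truth in enumerate(self.truths):
            gene = self.genes[[g.gene_id for g in self.genes].index(truth.gene_id)]
            is_carrier = carrier if isinstance(carrier, bool) else carrier.get(t_idx, False)
            ref_exons = sorted(gene.interval_g(a, b) for a, b in gene.exons_gs)
            alt_exons = sorted(truth.alt_exons)
            lo = min(truth.novel_junction[0], truth.hijacked_junction[0]) - 160
            hi = max(truth.novel_junction[1], truth.hijacked_junction[1]) + 160
            for r in range(depth):
                is_ir = rng.random() < ir_fraction
                has_allele = is_carrier and rng.random() < 0.5
                uses_novel = has_allele and (not is_ir) and rng.random() < truth.penetrance
                if is_ir:
                    # pre-mRNA molecules; fragments drawn around the variant,
                    # where they expose intronic variant bases
                    blocks = [(max(1, truth.pos - 80), min(len(chrom_seq), truth.pos + 80))]
                elif uses_novel:
                    blocks = [(max(s, lo), min(e, hi)) for s, e in alt_exons if e >= lo and s <= hi]
                    if truth.category == "ambiguous":
                        # expression stops shortly after the novel junction,
                        # leaving the far end of the gained run uncovered
                        if truth.hijacked_ss > truth.novel_ss:
                            cut = truth.novel_ss + 160
                            blocks = [(s, min(e, cut)) for s, e in blocks if s <= cut]
                        else:
                            cut = truth.novel_ss - 160
                            blocks = [(max(s, cut), e) for s, e in blocks if e >= cut]
                else:
                    blocks = [(max(s, lo), min(e, hi)) for s, e in ref_exons if e >= lo and s <= hi]
                blocks = [(s, e) for s, e in blocks if s <= e]
                if not blocks:
                    continue
                read = self._draw_read(rng, chrom_seq, blocks, read_length,
                                       truth if has_allele else None, error_rate,
                                       f"{sample_id}:{truth.gene_id}:{r}")
                if read is not None:
                    reads.append(read)
        junctions = self._tally_junctions(reads, min_overhang)
        return SimulatedSample(sample_id=sample_id, reads=reads, junctions=junctions)

    def _draw_read(self, rng, chrom_seq, blocks, read_length, truth, error_rate, read_id):
        total = sum(e - s + 1 for s, e in blocks)
        if total < read_length:
            return None
        q0 = int(rng.integers(0, total - read_length + 1))
        # map query interval [q0, q0+read_length) onto the template blocks
        out_blocks = []
        off = 0
        for s, e in blocks:
            blen = e - s + 1
            a = max(q0, off)
            b = min(q0 + read_length, off + blen)
            if a < b:
                out_blocks.append((s + (a - off), s + (b - off) - 1))
            off += blen
        seq = []
        for s, e in out_blocks:
            seq.append(chrom_seq[s - 1 : e])
        seq = list("".join(seq))
        if truth is not None:
            off = 0
            for s, e in out_blocks:
                if s <= truth.pos <= e:
                    seq[off + truth.pos - s] = truth.alt
                off += e - s + 1
        if error_rate > 0:
            for i in range(len(seq)):
                if rng.random() < error_rate:
                    seq[i] = str(rng.choice(_BASES))
        return ReadRecord(
            read_id=read_id,
            sequence="".join(seq),
            chrom=self.chrom,
            blocks=tuple(out_blocks),
            mapping_quality=60,
            base_qualities=tuple([40] * len(seq)),
        )

    def _tally_junctions(self, reads: Sequence[ReadRecord], min_overhang: int) -> list[SpliceJunction]:
        counts: dict[tuple[int, int], int] = {}
        for read in reads:
            for (s1, e1), (s2, e2) in zip(read.blocks, read.blocks[1:]):
                if e1 - s1 + 1 >= min_overhang and e2 - s2 + 1 >= min_overhang:
                    key = (e1 + 1, s2 - 1)
                    counts[key] = counts.get(key, 0) + 1
        out = []
        for (a, b), n in sorted(counts.items()):
            strand = self._strand_at(a)
            out.append(SpliceJunction(self.chrom, a, b, strand, n))
        return out

    def _strand_at(self, pos: int) -> str:
        for g in self.genes:
            if g.offset <= pos < g.offset + g.length:
                return g.strand
        return "undetermined"

    # -- fixture export ---------------------------------------------------

    def write_fixtures(self, outdir, samples: Sequence["SimulatedSample"] = ()) -> None:
        from sscv import io as gio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome = self.genome()
        gio.write_genome(genome, outdir / "genome.fa")
        self.write_gtf(outdir / "annotation.gtf")
        gio.write_repeats(self.repeats, outdir / "rmsk.tsv")
        gio.write_allele_frequencies(self.af_table(), outdir / "af.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump([t.to_dict() for t in self.truths], fh, indent=1)
        lengths = {name: len(seq) for name, seq in genome.sequences.items()}
        for s in samples:
            gio.write_junctions(s.junctions, outdir / f"{s.sample_id}.SJ.out.tab")
            gio.write_reads(s.reads, lengths, outdir / f"{s.sample_id}.sam")


@dataclass
class SimulatedSample:
    sample_id: str
    reads: list[ReadRecord]
    junctions: list[SpliceJunction]


# -- convenience wrappers mirroring the three top-level operations ---------


def simulate_reference(seed: int, n_genes: int = 4, **kwargs) -> SpliceSimulator:
    return SpliceSimulator(seed=seed, n_genes=n_genes, **kwargs)


def plant_sscv(sim: SpliceSimulator, scenario: Scenario, gene_index: Optional[int] = None) -> FixtureTruth:
    return sim.plant(scenario, gene_index)


def simulate_sample(sim: SpliceSimulator, sample_id: str, **kwargs) -> SimulatedSample:
    return sim.sample(sample_id, **kwargs)
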