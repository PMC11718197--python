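"""Readers and writers for every external format the pipeline touches.

All coordinates become 1-based inclusive at this boundary: GTF and
``SJ.out.tab`` already are; UCSC rmsk ``genoStart`` is 0-based and is
converted on read.  FASTA loading goes through pyfaidx, read records through
pysam; the GTF reader is line-based because GENCODE rows carry *repeated*
``tag`` attributes that DataFrame-shaped readers collapse.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import pyfaidx
import pysam

from sscv.models import (
    AFTable,
    ConsequenceCall,
    Genome,
    ReadRecord,
    RepeatElement,
    SpliceJunction,
    SSCVCall,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _open_text(path: PathLike):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: PathLike) -> Genome:
    """Load a FASTA file into an in-memory :class:`Genome`."""
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return Genome({name: str(fa[name][:]) for name in fa.keys()})


def write_genome(genome: Genome, path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(field: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for key, value in _ATTR_RE.findall(field):
        attrs.setdefault(key, []).append(value)
    return attrs


def read_annotation(path: PathLike) -> list[TranscriptModel]:
    """Parse a GENCODE-dialect GTF into transcript models.

    Only ``exon`` and ``CDS`` features are consulted; ``tag`` attributes
    (possibly repeated, e.g. ``MANE_Select``) are collected per transcript.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    spans: dict[str, tuple[int, int]] = {}
    n_skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields
            if feature not in ("transcript", "exon", "CDS"):
                continue
            attrs = _parse_attributes(attr_field)
            tx_ids = attrs.get("transcript_id")
            if not tx_ids:
                n_skipped += 1
                logger.warning("%s:%d: %s feature without transcript_id, skipped", path, lineno, feature)
                continue
            tx_id = tx_ids[0]
            start_i, end_i = int(start), int(end)
            m = meta.setdefault(
                tx_id,
                {
                    "gene_id": "",
                    "gene_name": "",
                    "chrom": chrom,
                    "strand": strand,
                    "tags": set(),
                    "biotype": "",
                },
            )
            if attrs.get("gene_id"):
                m["gene_id"] = attrs["gene_id"][0]
            if attrs.get("gene_name"):
                m["gene_name"] = attrs["gene_name"][0]
            if attrs.get("transcript_type"):
                m["biotype"] = attrs["transcript_type"][0]
            m["tags"].update(attrs.get("tag", []))
            if feature == "transcript":
                spans[tx_id] = (start_i, end_i)
            elif feature == "exon":
                exons.setdefault(tx_id, []).append((start_i, end_i))
                span = spans.get(tx_id)
                if span and not (span[0] <= start_i and end_i <= span[1]):
                    logger.warning(
                        "%s:%d: exon %d-%d outside declared span of %s, record kept",
                        path, lineno, start_i, end_i, tx_id,
                    )
            else:
                cds.setdefault(tx_id, []).append((start_i, end_i))

    out = []
    for tx_id, ex in exons.items():
        m = meta[tx_id]
        cds_start = cds_end = None
        if tx_id in cds:
            cds_start = min(s for s, _ in cds[tx_id])
            cds_end = max(e for _, e in cds[tx_id])
        out.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=m["gene_id"],
                gene_name=m["gene_name"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(sorted(ex)),
                cds_start=cds_start,
                cds_end=cds_end,
                tags=frozenset(m["tags"]),
                biotype=m["biotype"],
            )
        )
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


# ---------------------------------------------------------------------------
# STAR SJ.out.tab

_SJ_STRAND = {"0": "undetermined", "1": "+", "2": "-"}


def read_junctions(path: PathLike) -> list[SpliceJunction]:
    """Parse a STAR ``SJ.out.tab`` file.

    Columns: chrom, intron first base, intron last base, strand code
    (0 undetermined / 1 plus / 2 minus), motif, annotated, unique reads,
    multimapped reads, max overhang.  Unique reads = column 7.
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 SJ.out.tab columns, got {len(fields)}"
                )
            chrom, start, end, strand_code = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = _SJ_STRAND.get(strand_code)
            if strand is None:
                raise ValueError(f"{path}:{lineno}: bad strand code {strand_code!r}")
            out.append(
                SpliceJunction(
                    chrom=chrom,
                    intron_start=start,
                    intron_end=end,
                    strand=strand,
                    unique_reads=int(fields[6]),
                )
            )
    return out


def write_junctions(junctions: Sequence[SpliceJunction], path: PathLike) -> None:
    """Write junctions in SJ.out.tab layout (motif/annotated columns zeroed)."""
    code = {"+": "1", "-": "2", "undetermined": "0"}
    with open(path, "w") as fh:
        for j in sorted(junctions, key=lambda j: (j.chrom, j.intron_start, j.intron_end)):
            fh.write(
                "\t".join(
                    [j.chrom, str(j.intron_start), str(j.intron_end), code[j.strand],
                     "0", "0", str(j.unique_reads), "0", "0"]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# UCSC rmsk


def read_repeats(path: PathLike, family: Optional[str] = None) -> list[RepeatElement]:
    """Parse a UCSC RepeatMasker dump (with or without the leading bin columns).

    ``genoStart`` is 0-based and converted to a 1-based inclusive start.
    Optionally restrict to one ``repFamily`` (e.g. ``"Alu"``).
    """
    out = []
    n_bad = 0
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                if len(f) >= 17:  # full rmsk dump: genoName at index 5
                    chrom, start, end, strand = f[5], int(f[6]), int(f[7]), f[9]
                    rep_name, rep_class, rep_family = f[10], f[11], f[12]
                elif len(f) >= 7:  # trimmed table
                    chrom, start, end, strand = f[0], int(f[1]), int(f[2]), f[3]
                    rep_name, rep_class, rep_family = f[4], f[5], f[6]
                else:
                    raise ValueError("too few columns")
                elem = RepeatElement(
                    chrom=chrom, start=start + 1, end=end, strand=strand,
                    rep_name=rep_name, rep_class=rep_class, rep_family=rep_family,
                )
            except (ValueError, IndexError):
                n_bad += 1
                continue
            if family is None or elem.rep_family == family:
                out.append(elem)
    if n_bad:
        logger.warning("read_repeats: skipped %d malformed rows", n_bad)
    return out


def write_repeats(repeats: Sequence[RepeatElement], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(
                "\t".join(
                    [r.chrom, str(r.start - 1), str(r.end), r.strand,
                     r.rep_name, r.rep_class, r.rep_family]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Allele frequencies


def read_allele_frequencies(path: PathLike) -> AFTable:
    """Read a chrom/pos/ref/alt/AF TSV, or a sites VCF with an AF INFO key."""
    path = str(path)
    table = AFTable()
    with _open_text(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        vcf = pysam.VariantFile(path)
        for rec in vcf:
            afs = rec.info.get("AF")
            if afs is None:
                continue
            if not isinstance(afs, (tuple, list)):
                afs = (afs,)
            for alt, af in zip(rec.alts or (), afs):
                table.add(rec.chrom, rec.pos, rec.ref, alt, float(af))
        return table
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns chrom,pos,ref,alt,af")
            try:
                table.add(f[0], int(f[1]), f[2], f[3], float(f[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_allele_frequencies(table: AFTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        for (chrom, pos, ref, alt), af in sorted(table.items()):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{af}\n")


# ---------------------------------------------------------------------------
# Reads (SAM)


def read_reads(path: PathLike) -> list[ReadRecord]:
    """Load aligned reads from SAM/BAM into :class:`ReadRecord` objects."""
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            blocks = tuple((s + 1, e) for s, e in aln.get_blocks())
            quals = tuple(aln.query_qualities) if aln.query_qualities is not None else None
            out.append(
                ReadRecord(
                    read_id=aln.query_name,
                    sequence=aln.query_sequence,
                    chrom=aln.reference_name,
                    blocks=blocks,
                    mapping_quality=aln.mapping_quality,
                    base_qualities=quals,
                )
            )
    return out


def write_reads(reads: Sequence[ReadRecord], genome_lengths: dict[str, int], path: PathLike) -> None:
    """Write reads as headered SAM (CIGAR rebuilt from the block structure)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in genome_lengths.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.reference_name = r.chrom
            a.reference_start = r.blocks[0][0] - 1
            a.mapping_quality = r.mapping_quality
            cigar = []
            for i, (s, e) in enumerate(r.blocks):
                if i:
                    cigar.append((3, s - r.blocks[i - 1][1] - 1))  # N
                cigar.append((0, e - s + 1))  # M
            a.cigartuples = cigar
            if r.base_qualities is not None:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in r.base_qualities)
                )
            fh.write(a)


# ---------------------------------------------------------------------------
# Result tables

RESULT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "side", "relative_position",
    "strand", "intron_start", "intron_end", "matching_ss", "primary_novel_ss",
    "junction_reads", "mismatch_reads", "realign_support", "population_af",
    "gene", "transcript", "category", "hijacked_ss", "secondary_ss",
    "size_change", "frame", "ptc", "nmd", "hgvs_p", "utr_only",
]

_VCF_INFO_KEYS = ["SSCV_SIDE", "REL_POS", "CONSEQ", "FRAME", "PTC", "NMD", "HGVSP", "GENE", "TX"]


def _result_row(call: SSCVCall, conseq: Optional[ConsequenceCall], gene: str) -> dict:
    v = call.variant
    j = v.pnj.junction
    c = conseq or ConsequenceCall(category="")
    return {
        "sample_id": call.sample_id,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref_base,
        "alt": v.alt_base,
        "side": v.side,
        "relative_position": v.relative_position,
        "strand": v.pnj.strand,
        "intron_start": j.intron_start,
        "intron_end": j.intron_end,
        "matching_ss": v.pnj.matching_ss.pos,
        "primary_novel_ss": v.pnj.primary_novel_ss.pos,
        "junction_reads": v.pnj.unique_reads,
        "mismatch_reads": v.mismatch_reads,
        "realign_support": v.realign_support,
        "population_af": call.population_af,
        "gene": gene,
        "transcript": c.reference_transcript_id or "",
        "category": c.category,
        "hijacked_ss": "" if c.hijacked_ss is None else c.hijacked_ss,
        "secondary_ss": "" if c.secondary_ss is None else c.secondary_ss,
        "size_change": c.size_change,
        "frame": c.frame,
        "ptc": c.ptc,
        "nmd": c.nmd,
        "hgvs_p": c.hgvs_p or "",
        "utr_only": str(c.utr_only).lower(),
    }


def write_results(
    calls: Sequence[tuple[SSCVCall, Optional[ConsequenceCall]]],
    path: PathLike,
    fmt: str = "tsv",
    genome: Optional[Genome] = None,
    gene_names: Optional[dict[str, str]] = None,
) -> None:
    """Write (call, consequence) pairs as a TSV or a VCF 4.2 file.

    Rows are ordered by (chrom, pos, alt, sample) so repeated runs are
    byte-identical.
    """
    gene_names = gene_names or {}
    rows = []
    for call, conseq in calls:
        tx = conseq.reference_transcript_id if conseq else None
        gene = gene_names.get(tx or "", "")
        rows.append(_result_row(call, conseq, gene))
    rows.sort(key=lambda r: (r["chrom"], r["pos"], r["alt"], r["sample_id"]))
    if fmt == "tsv":
        df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "vcf":
        _write_vcf(rows, path, genome)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_vcf(rows: list[dict], path: PathLike, genome: Optional[Genome]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SSCV_SIDE,Number=1,Type=String,Description="Created splice site side">\n')
        fh.write('##INFO=<ID=REL_POS,Number=1,Type=Integer,Description="Variant position relative to the novel splice site">\n')
        fh.write('##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Splicing consequence category">\n')
        fh.write('##INFO=<ID=FRAME,Number=1,Type=String,Description="in_frame or frameshift">\n')
        fh.write('##INFO=<ID=PTC,Number=1,Type=String,Description="Premature termination codon status">\n')
        fh.write('##INFO=<ID=NMD,Number=1,Type=String,Description="NMD susceptibility (50 bp rule)">\n')
        fh.write('##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein-level change">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">\n')
        fh.write('##INFO=<ID=TX,Number=1,Type=String,Description="Reference transcript">\n')
        if genome is not None:
            for name, seq in genome.sequences.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in rows:
            info_vals = {
                "SSCV_SIDE": r["side"], "REL_POS": r["relative_position"],
                "CONSEQ": r["category"] or ".", "FRAME": r["frame"], "PTC": r["ptc"],
                "NMD": r["nmd"], "HGVSP": r["hgvs_p"] or ".", "GENE": r["gene"] or ".",
                "TX": r["transcript"] or ".",
            }
            info = ";".join(f"{k}={info_vals[k]}" for k in _VCF_INFO_KEYS)
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t{info}\n"
            )


def read_results(path: PathLike) -> pd.DataFrame:
    """Re-parse a result TSV (round-trips :func:`write_results`)."""
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, keep_default_na=False,
        na_values=[], converters={"hijacked_ss": str, "secondary_ss": str, "hgvs_p": str},
    )
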