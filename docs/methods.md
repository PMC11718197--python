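# Methods

## Coordinate and splice-site conventions

All internal coordinates are 1-based inclusive, matching `SJ.out.tab` and
GTF; the UCSC rmsk table's 0-based `genoStart` is converted on read. A
splice site is identified by its intron-terminal base: the donor is the
first intron base, the acceptor the last, both in transcript direction (so
on the minus strand the donor is the genomic `intron_end`). Junction
identity — for panels and membership tests — is `(chrom, intron_start,
intron_end)`; the strand is stored but not part of the key, because STAR
reports one record per intron and panel membership is positional. All
strand-aware sequence access goes through one `Genome.fetch` accessor, so
motif logic never hand-rolls reverse complements; minus-strand rules are
applied by mirroring into transcript coordinates, never re-derived.

## Junction screening

A junction qualifies as a primary novel junction when exactly one edge
matches an annotated boundary. When the matching edge is within the margin
(default 5 bp) but not exact, both intron coordinates are shifted by the
same offset, preserving intron length: the ≤ 5 bp discrepancy arises from
alignment sliding at repeated bases, which moves both edges together. Among
multiple in-margin boundaries the smallest |offset| wins, ties going to the
smaller coordinate. If both edges are within margin of annotations but
neither is exact, the junction is treated as a slid annotated junction and
dropped (conservative). The strand of the novel junction is inherited from
the matched transcript, overriding the `SJ.out.tab` strand code; junctions
with strand code 0 are retained and resolved the same way.

The four exclusion filters use unique reads only (`SJ.out.tab` column 7).
The 5 % share is computed against all junctions whose *same-side* intron
terminal equals the matching splice-site coordinate — a junction whose
opposite terminal coincidentally lands on the coordinate does not share the
splice site. "Intersecting" means ≥ 1 bp of intron-interval overlap with
any other junction record of the sample, annotated or not, at any read
count. Panel membership is tested on both the adjusted and the raw observed
key, so an alignment-slid copy of a panelled junction stays excluded.

## Motif model and candidate enumeration

Donor consensus `AG | GTRAGT`: allowed bases A at −2, G at −1, then
G, T, A/G, A, G, T at +1…+6, with `GT` at +1/+2 required *after* the
substitution. Acceptor consensus `YYNYAG | R`: C/T at −6, −5, −3 (any base
at −4), A at −2, G at −1, A/G at +1, with `AG` at −2/−1 required after the
substitution. A candidate is any single-base substitution whose reference
base is outside the allowed set, whose alternative is inside it, and after
which the essential dinucleotide holds. Only SNVs are enumerated — the
motif rules as written are substitutions; indels are out of scope.
Mismatch support uses conservative pileup gates (base quality ≥ 15, mapping
quality ≥ 20) that the underlying method leaves unstated; both are
configurable.

## Realignment validation

"Reads surrounding the position" are reads whose reference envelope —
spliced gaps included — covers the variant, because junction reads skip the
base yet span it. Mini-transcripts are built on the genome plus strand
(read sequences are stored SAM-style on the plus strand): junction-spanning
templates take 10 bases from each edge (20-mers), the intron-retention
template 10 bases either side of the variant (21-mer). A with-variant
version exists only where the window covers the variant position. With
several reference junctions sharing the matching splice site, each yields
its own template; ties among them go to the template from the longest
transcript, then lexicographic sequence — assignment is invariant to the
input order of templates. Alignment is infix (the template must occur
within the read; shorter reads are skipped) with edit distance ≤ 2. The
"no mutations within 5 bp of the variant" guard is applied to *every*
template whose window covers the variant position, including the
without-variant versions; this is what forces variant-carrying reads onto
with-variant templates instead of being absorbed as near-misses.

A variant appearing under several novel junctions in one sample is reported
once, keeping the junction with the most supporting reads. Sample-level QC
(`flag_sample_qc`) flags samples with an extreme number of calls (default
50, configurable) as potential DNA contamination; it is a post-hoc flag,
not a filter.

## Consequence classification

The reference transcript is chosen by MANE Select > MANE Plus Clinical >
largest transcript > earlier transcript ID. The affected exon and hijacked
splice site follow the donor/acceptor definitions mirrored onto transcript
direction. For cryptic exons the secondary edge must lie strictly between
the hijacked site and the novel site, within 300 bp of the novel site
inclusive, leaving at least one exonic base; among several qualifying
junctions the most-supported wins, ties to the nearest (≥ 1 unique read
required). The new-exon size is the inclusive distance between the two
intron-terminal-adjacent exonic bases. Exon extension demands depth ≥ 1 at
*every* base from the hijacked site to the novel site, computed from read
blocks.

The altered mRNA is reconstructed from the *reference* genome plus the new
exon structure; the variant base itself is not substituted. This is
deliberate: it reproduces the "apparent nonsense rescue" behaviour, where a
variant that would read as a stop codon is removed by the splicing change
it causes, so the transcript-level verdict must not depend on the variant
base. Changes wholly outside the CDS genomic span are flagged UTR-only and
skipped; events deleting the start or stop codon are flagged and skipped.
Frame is the mature-transcript size change modulo 3. PTC status compares
the first stop of the altered CDS against the homologous position of the
original stop (original offset shifted by the size change); a stop at or
beyond the homologous position — including the rare frameshift that finds
its stop later — is non-PTC. The 50 bp rule: a PTC strictly less than 50 nt
upstream of the last exon-exon junction, or downstream of it, escapes NMD;
exactly 50 nt is susceptible; single-exon transcripts escape. Protein
changes are minimal del/ins/delins descriptions anchored at the diverging
residues, novel residues rendered `X[n]`, frameshifts as `fs`.

## Alu coordinate mapping

Elements (consensus orientation; minus-strand elements reverse-complemented)
are globally aligned to the reference Alu with match +1, mismatch −1, gap
open −5, gap extend −2. The gap penalties are deliberately stiffer than a
generic default: with cheap gaps an unrelated sequence (e.g. the reverse
complement) can gap around mismatches and inflate its matched-column
identity above 50 %, defeating the low-quality flag. Identity is matches
over all alignment columns, gaps included; below 0.5 the hit is flagged and
excluded from cluster counts. Cluster counting deduplicates to distinct
variants (a variant recurring across samples counts once) per (consensus
position of the novel splice site, side, orientation), threshold > 50.
Orientation compares element strand with the transcript strand of the
call. Alu families are the first four characters of `repName`
(AluJ/AluS/AluY, otherwise "other"). The reference Alu consensus is an
input FASTA, never embedded.

## Statistics

The one-sided rank-sum test (carriers' novel-junction ratios greater — the
biologically meaningful direction, since the variant creates the junction)
uses exact enumeration when the smaller group has ≤ 8 tie-free observations
and the normal approximation with tie correction otherwise
(scipy `mannwhitneyu` backend; tests cross-check full enumeration).
Fisher's method computes −2Σln p against the upper chi-square tail with 2k
degrees of freedom, p-values clamped at 1e-300 before the log. The
germline/somatic triage is a configurable decision tree with documented
defaults (normal depth < 8 → Ambiguous; tumour failing the > 2 reads and
> 5 % rule → False positive; normal VAF ≥ 0.25 → Germline; zero normal
support → Somatic; else Somatic-or-germline); the thresholds are
placeholders in the sense that the source flowchart is not restated here,
and the category vocabulary is fixed to those five labels.

## The simulator

The simulator is the package's study condition, not a tuning dial. Genes
have 3–5 exons of 120–180 bp and introns of 550–750 bp with canonical
`GT…AG` boundaries; each carries one MANE-Select protein-coding transcript
with a 60 nt 5′ UTR, an ATG…TAA CDS built from stop-free codons, and a 3′
UTR in the last exon. Scenarios plant one variant per gene: the essential
dinucleotide of the motif-to-be is written, the variant position gets a
disallowed reference base (stop-inert bases preferred), and a repair pass
guarantees the reference CDS still terminates at its intended stop.
Gained/cryptic intervals are filled T-free so no stop codon can arise
inside them unless `force_ptc` plants an in-frame `TAA`; reading-frame
interactions at interval boundaries can still produce a stop, in which case
the analytically computed truth records it. "Ambiguous" scenarios use
extension geometry with expression clipped shortly after the novel
junction, leaving the far end of the gained run uncovered.

Sampling draws `depth` reads per planted locus: molecules are heterozygous
(variant allele probability 0.5 in carriers), variant-allele molecules use
the novel junction with probability `penetrance`, and a fraction
(default 0.12) are intron-retaining pre-mRNA fragments drawn around the
variant — the mechanism by which deep-intronic variant bases become visible
in RNA at all. Sequencing errors are i.i.d. substitutions (no indels, the
pipeline's scope). Junction tables are tallied from the generated reads
with a STAR-like 8 bp minimum overhang. Everything derives from one
integer seed and regenerates byte-identically.

What the simulator does *not* emulate: expression-level variation between
genes, GC and positional coverage bias, fragment-length distributions,
multi-mapping, indel errors, alternative annotated isoforms, or
alignment errors. Passing tests therefore demonstrate the correctness of
the screening, enumeration, validation and classification logic under clean
evidence, not robustness to real-library artefacts.

The synthetic Alu-like consensus is a dimer built for structural realism —
a 130 nt left arm, a 5 nt A-linker, a right arm duplicating the left with a
31 nt internal insert after position 40, and a poly-A tail — so arm-to-arm
correspondence has a known oracle: left-arm positions before the insert map
to right-arm positions shifted by exactly 135 (e.g. 22 ↔ 157). It is not
the published Alu consensus, which the package takes as an input file.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 25–50 carrier and
variant-free samples over 12 planted scenarios (all four categories ×
penetrances 0.2/0.5/1.0) at read depth 60, chosen so the whole suite
completes in well under a minute on one CPU while every scenario is
exercised at evidence levels both above and below the calling thresholds.
Recall is therefore *evidence-conditioned*: a planted variant is required
to be called exactly when its simulated junction support (≥ 3 reads) and
mismatch support (≥ 2 reads) materialised in that sample, and category
recovery is asserted when the category's own evidence (full coverage of the
gained run; an observed secondary junction) is present — the conditioning
mirrors the detector's stated thresholds, nothing else. Specificity on
variant-free samples is absolute (zero calls).

## Known limitations

- Only single-nucleotide substitutions are considered; motif-creating
  indels are out of scope.
- One reference transcript interprets each event; effects on other isoforms
  of the same gene are not reported.
- NMD prediction is the 50 bp rule only.
- The germline/somatic thresholds are defaults, not calibrated values.
- The HGVS output is the minimal protein-level description (`del`, `ins`,
  `delins`, `fs`, `X[n]` for novel residues), not a full nomenclature
  engine.
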