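# sscv — splice-site creating variants from transcriptome evidence

`sscv` detects **splice-site creating variants (SSCVs)** — single-nucleotide
substitutions that build a new splice donor or acceptor motif — directly from
RNA-seq evidence: the per-sample splice-junction table produced by the STAR
aligner (`SJ.out.tab`) plus the aligned reads. No DNA sequencing is needed;
the variant itself is read off mismatch bases in the transcriptome, which is
what makes the approach applicable to the enormous public RNA-seq archives.
The package is aimed at researchers studying aberrant splicing in rare
disease and cancer who want to call, validate and interpret such variants,
and at method developers who need a fully synthetic, ground-truthed test bed
for splicing-variant callers.

## What it computes

1. **Aberrant junction screening.** A junction is a *primary novel splicing
   junction* when one edge matches an annotated exon-intron boundary (within
   a 5 bp margin, to absorb alignment sliding) and the other edge matches no
   annotation. Four filters remove noise: fewer than 3 supporting reads;
   membership in a *control panel* of junctions recurrently seen in reference
   cohorts (≥ 2 reads in ≥ 4 samples, or per-tissue ≥ 2 reads in ≥ 8
   individuals); a share below 5 % of all reads at the matching splice site;
   and 5 or more intersecting junctions.

2. **Motif-creating variant enumeration.** For each surviving junction the
   candidate substitutions are those that move the sequence at the novel
   splice site toward the consensus motif — donor `AG | GTRAGT`, acceptor
   `YYNYAG | R` (`|` the exon-intron boundary) — with the essential `GT` /
   `AG` dinucleotide required after the substitution. A candidate needs ≥ 2
   mismatch-supporting reads (base quality ≥ 15, mapping quality ≥ 20).

3. **Realignment validation.** Up to six 20/21-mer *mini-transcripts* are
   built per candidate (primary novel, reference, and intron-retention
   templates, each with and without the variant base). Every read around the
   variant is infix-aligned to each template with edlib; alignments need edit
   distance ≤ 2 and no edit within 5 bp of the variant. Ties resolve in a
   fixed conservative order (reference-without first, primary-novel-with
   last). The candidate survives if at least one read prefers a with-variant
   template. Variants with population allele frequency > 0.01 are removed.

4. **Consequence classification.** On a reference transcript (MANE Select >
   MANE Plus Clinical > largest), the event is *partial exon loss* (novel
   site inside the affected exon), *cryptic exon* (a junction links the
   hijacked splice site to a secondary site within 300 bp of the novel one),
   *exon extension* (read depth ≥ 1 across the whole hijacked-to-novel run),
   or *ambiguous*. The altered mRNA is reconstructed to call frame
   (size change mod 3), premature termination (first stop before the
   homologous original stop), NMD susceptibility (the 50 bp rule against the
   last exon-exon junction) and an HGVS-style protein change with novel
   residues written `X[n]`.

5. **Alu exonization.** SSCVs inside RepeatMasker Alu elements (≥ 200 bp)
   are mapped through a pairwise alignment onto reference-Alu coordinates;
   recurrent positions form hotspot clusters (> 50 distinct SSCVs), and the
   two arms of the dimeric consensus are aligned to each other to relate
   left-arm and right-arm hotspots.

6. **Evaluation statistics.** Novel-junction usage ratios, one-sided
   Wilcoxon rank-sum tests per tissue, Fisher's combination across tissues,
   the DNA-level confirmation rule (> 2 reads and > 5 % of coverage), and a
   germline/somatic triage from tumour and matched-normal pileups.

A deterministic simulator (`sscv.simulate`) builds miniature genomes with
planted SSCVs of every category and analytically known consequences, so the
entire pipeline is testable offline.

## Worked example

```bash
sscv simulate --seed 5 --n-samples 1 --out fx
sscv detect   --sj fx/S1.SJ.out.tab --sam fx/S1.sam --genome fx/genome.fa \
              --gtf fx/annotation.gtf --af fx/af.tsv --sample-id S1 --out calls.tsv
sscv classify --calls calls.tsv --sj fx/S1.SJ.out.tab --sam fx/S1.sam \
              --genome fx/genome.fa --gtf fx/annotation.gtf --out classified.tsv
```

yields three calls (one per planted scenario):

```
chrom  pos ref alt     side  relative_position          category  size_change      frame     ptc            nmd          hgvs_p
 chrS 1315   C   G    donor                 -1 partial_exon_loss          -50 frameshift     ptc    susceptible           V61fs
 chrS 6210   T   G acceptor                 -3    exon_extension          129   in_frame non_ptc not_applicable H85_D86insX[43]
 chrS 9264   C   G    donor                  5      cryptic_exon          102   in_frame     ptc    susceptible     S88_G197del
```

Reading the second row: a substitution at intronic position −3 of a newly
created acceptor extends the exon by 129 bp; 129 is a multiple of three, the
inserted stretch contains no stop codon, so the protein gains 43 novel
residues (`insX[43]`) between its 85th and 86th residues and the original
stop codon is untouched. The first row loses 50 exonic bases — a frameshift
generating a premature termination codon more than 50 nt upstream of the
last exon-exon junction, hence predicted NMD-susceptible. The third inserts
a 102 bp cryptic exon that happens to carry an in-frame stop.

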