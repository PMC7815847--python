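# Methods

## Overview

`ipaseq` quantifies polyA-site usage from 3′-end sequencing of the
3′READS+ family, in which reads are sequenced through the residual
oligo-T stretch left by the poly(A) tail, so that the T/insert junction
marks the cleavage position. The pipeline assumes strand-specific,
single-end reads laid out as UMI + T tail + reverse complement of the
transcript 3′ end, with the 5′ adapter already removed. All coordinates
are 0-based half-open internally; a cleavage position is the 0-based
coordinate of the last transcribed base, and "downstream" always means
transcription direction. GTF is converted from its 1-based inclusive
convention on read and write; BED is native.

## PASS-read extraction

**Trimming.** The first `umi_length` (default 4) bases are removed as the
UMI. The maximal leading run of T's is then consumed as the tail; one
embedded non-T base is tolerated provided at least one T follows it, which
matches a single sequencing or RT error inside an otherwise pure T
stretch. Reads whose remaining insert is shorter than `min_insert`
(default 22 nt) are rejected — shorter inserts align too promiscuously to
be informative.

**Alignment.** Real libraries should be aligned externally end-to-end and
ingested as SAM/BAM (`load_alignments`; unmapped, secondary and
supplementary records are dropped, and `min_mapq` = 10 is the quality
floor). For simulation and tests the package ships an exact aligner over a
20-mer seed index: a unique full-length exact match on either strand gets
MAPQ 42, multiple matches MAPQ 0 (then removed by the MAPQ floor), no
match is unaligned. These MAPQ values are a declared dialect of this
aligner, not a model of any external tool's scores.

**Tail rescue and classification.** The insert is the reverse complement
of the transcript, so the transcript strand is opposite the insert's
alignment strand, and the provisional cleavage position is the alignment
end (transcript +) or start (transcript −). Genuine cleavage sites can sit
immediately upstream of genomic A's; tail bases that merely copy those
genomic A's must not count as tail evidence. Rescue therefore walks the
tail from its insert-adjacent base outward, comparing each tail base with
successive genomic sense-strand bases downstream (up to `rescue_window` =
20 bp, truncated at contig ends): a tail T matches a genomic A, a tail
non-T matches only its complement. Every rescued base moves the cleavage
one base downstream; the first mismatch stops the walk. The rescue rule is
sometimes stated as reading "from the start of the T tail"; only the
insert-adjacent end of the tail can correspond to contiguous genomic
sequence, so the walk starts there — the opposite reading has no physical
interpretation. A rescued non-T repositions the cleavage exactly like a
rescued T; an unrescued non-T never counts as an unmappable T.

A read is **PASS** when at least two tail T's remain unexplained by
genomic A's. Non-PASS reads are partitioned into `internal_priming`
(something was rescued), `insufficient_tail` (nothing rescued, fewer than
two tail T's) and `tailless` (no tail at all); together with the trimming
and alignment rejections these categories partition every input read,
which the tests assert.

This trimming/rescue pair is self-correcting in a useful way: when a
transcript ends in genomic A's, the read's insert begins with T's that the
trimmer absorbs into the tail, shortening the alignment; rescue then walks
the cleavage right back to the true position. The simulator relies on this
and the test suite verifies exact positional recovery.

## Site calling

**Clustering.** PASS cleavage positions on the same contig and strand are
clustered by single linkage with a 24-nt merge window: sorted positions
are chained while consecutive gaps are ≤ 24. The representative position
is the member with the highest pooled read count — the mode is robust to
the ±1–2 nt micro-heterogeneity of real cleavage — with ties broken toward
the 5′-most position in transcript orientation for reproducibility.
Per-library counts are summed over the cluster.

**Filters** run in a fixed order: exclusion intervals → gene assignment →
robustness → annotation → re-annotation → ambiguous-overlap removal, and
every stage records input / per-reason removals / retained, so the ledger
conserves counts at each step.

- *Exclusion intervals*: a site whose representative position lies in any
  labelled interval set (blacklist, retrotransposons, miRNA, snoRNA) is
  flagged with every covering label and removed once. Overlap is half-open
  on the single-base site interval.
- *Gene assignment*: a gene's span is [min exon start, max exon end) with
  no padding — the simplest defensible rule; it is configurable by editing
  the models. Sites covered by no same-strand span are intergenic; sites
  covered by two or more are unattributable and removed.
- *Robustness*: a site is kept only if (1) its host gene has ≥ 5 RNA-seq
  counts in at least one condition, (2) its replicate-sum count reaches 10
  in at least one condition, and (3) its FPU reaches 10% in at least one
  library. Genes missing from the RNA-seq table count as zero and are
  logged.
- *Annotation*: intron takes priority over 3′UTR, then exon, so
  previously uncharacterized intronic sites are not mislabelled as UTR by
  overlapping annotations. Genes that retain exactly one site have that
  site re-annotated as 3′UTR regardless of prior label (a lone surviving
  site is almost always the gene's true end); the adjustment counts are
  reported split by prior category, and the operation is idempotent.
- *Ambiguous overlaps*: positions where two or more gene spans of the
  pre-filter annotation overlap are removed even when only one of those
  genes survived earlier filters, because reads there cannot be attributed
  with confidence.

**AAUAAA scan.** As a light-weight motif check, the scanner reports the
fraction of sites with AATAAA in the 40 bp of transcript-sense sequence
immediately upstream of cleavage, plus a one-sided binomial p-value
against the null hit rate 1 − (1 − q)^35, where q = f_A⁵ · f_T under the
pooled base composition of the ±200 bp windows. This replaces a full
motif-enrichment search and is intended for QC, not discovery.

## FPU statistics and differential calling

FPU (fraction of polyA-site usage) is the site count divided by the summed
counts of all the gene's sites, per library; per gene and library the FPU
vector sums to 1 and is invariant to rescaling a library's counts, which
the tests assert to 1e-9 on random matrices. Genes with zero counts in a
library yield NA for that library only.

**Differential usage** between two conditions is threshold-driven. The
operative statistic is the fold change of replicate-mean FPU,
fc = (mean FPU_B + ε) / (mean FPU_A + ε) with ε = 1e-4 guarding silent
sites; "down" means reduced usage in condition B. When a gene is silent in
a whole condition its mean is floored to 0 and the site flagged
`one_condition`. The accompanying p-value is a two-sided Fisher exact test
on the pooled 2×2 table [site count, rest-of-gene count] × [A, B].
Count-model packages built for gene-level counts are statistically
ambiguous when applied to within-gene fractions, so this package uses the
exact site-versus-rest test as its documented stand-in; p-values are
reported raw alongside the threshold-based calls, and the test suite
verifies them against full hypergeometric enumeration.

**Differential IpA calls** require, jointly: category intron; FPU fold
change ≥ 2 (or ≤ 1/2); RNA-seq ±100 bp window fold change ≥ 1.5 in the
same direction (pseudocount 1, depth-scaled by total mapped reads — both
choices configurable); and more RNA-seq counts upstream than downstream of
the site. The upstream/downstream check uses 100-bp flanks in transcript
orientation — upstream ends at and includes the cleavage base, downstream
starts just after it — evaluated on the pooled reads of the condition with
the higher mean FPU, where the IpA isoform's coverage shelf is most
visible. Window and condition choice are the package's own conventions;
per-criterion booleans are retained so a failed call shows which rule
failed. Sites lacking window counts are excluded and counted.

**Knockdown dependence** keeps calls whose knockdown-versus-control FPU
fold change passes 1.5 in the same direction as the differentiation call.
**Distal 3′UTR usage** is computed for genes with ≥ 2 3′UTR sites: the
distal fraction is the 3′-most site's share of the gene's 3′UTR counts,
replicates pooled per condition; its fold change classifies genes as
lengthened (> 1.5), shortened (< 1/1.5) or unchanged. **DE-table
intersection** consumes externally produced differential-expression tables
(gene, log2fc, pvalue) and returns genes passing fold change ≥ 2 and
p < 0.05 in both tables with concordant direction.

## Synthetic data

The generator emulates a two-condition (UD/DF), two-replicate 3′READS+
study with matched RNA-seq, optionally extended with a knockdown pair
(CTRL/KD). Its defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 200 | three-exon, single-isoform genes on two contigs, both strands |
| gene_length_range | 1200–2000 bp | total span; intron 1 ≥ 260 bp |
| reads_per_library | 50,000 | exact emitted read count |
| replicates_per_condition | 2 | |
| tail_length_distribution | uniform 8–20 nt | residual T-tail lengths (configurable over 2–30) |
| non_t_error_prob | 0.15 | one tail substitution, never insert-adjacent |
| internal_priming_fraction | 0.05 | reads generated at decoy A-runs |
| umi_length / insert_length | 4 / 40 nt | read layout |
| ipa_gene_fraction | 0.4 | genes with an intron-1 site |
| differential_fraction | 0.5 | of IpA genes: usage shifts 0.6↔0.2 (a 3× FPU change) |
| down_fraction | 0.6 | of shifts: usage drops in DF |
| two_utr3_fraction | 0.5 | of non-IpA genes: tandem 3′UTR sites 120 bp apart |
| distal_shift_fraction | 0.5 | of tandem genes: distal fraction 0.3↔0.7 |
| knockdown_responsive_fraction | 0.4 | differential sites that shift the same way in KD |

Each planted site carries an AATAAA hexamer 10–40 bp upstream and a forced
non-A base immediately downstream, so tail rescue stops exactly at the
planted position. Decoys are 35-base genomic A-runs (both strands) whose
reads carry tails drawn entirely from the run, capped at the rescue
window; guard bases upstream of each decoy keep the trimmer out of the
decoy insert. Gene expression is log-normal (σ = 0.6), identical across
conditions so that FPU shifts are the only between-condition signal.

RNA-seq reads are single-end genomic intervals drawn uniformly along
spliced isoforms (an IpA isoform retains intron sequence up to its
cleavage site), with molecule weights expression × usage × transcript
length so per-base coverage tracks abundance, truncated at block
boundaries (no junction reads). An optional `pre_mrna_fraction` mixes in
unspliced pre-mRNA coverage; the default is 0, giving a sharp coverage
shelf at used IpA sites. With a pre-mRNA fraction ρ the analytic
upstream:downstream coverage ratio at an IpA site of usage u is
(u(1−ρ)+ρ)/ρ — exactly 2.0 at u = 0.5, ρ = 1/3 — which the tests verify.

What the generator does **not** emulate: base-call errors outside the
single tail substitution, quality-score variation, multi-isoform splicing
graphs, paired ends, GC or positional bias, between-condition expression
changes, and empirical tail-length distributions (not publicly reported
for this protocol; the uniform default is configurable). Passing tests
therefore demonstrate the correctness of the algorithms and their
bookkeeping under clean generative assumptions, not robustness to every
artifact of real libraries — real data should be aligned with an external
end-to-end aligner and fed in as SAM/BAM.

## Numerical and scale choices

- ε = 1e-4 for fold-change floors; pseudocount 1 for window ratios;
  FPU sums asserted to 1e-9.
- Deterministic ordering everywhere: sites sorted by (chrom, position,
  strand); clustering ties break 5′-most; all randomness flows from
  explicit seeds (per-library seeds derive from the config seed, the
  condition index and the replicate index).
- The default validation study is 200 genes × 2 conditions × 2 replicates
  × 50,000 reads with RNA-seq depth 100,000 per condition. Power and
  specificity are measured on 20 (power) and 10 (null) stochastic
  replicates of a 50-gene, 10,000-read world — scaled so the whole suite
  runs in a couple of minutes on one CPU while keeping ≥ 100 planted
  events per estimate.

## Known limitations

- The exact aligner only finds full-length exact matches; reads crossing
  splice junctions or carrying internal errors require an external
  aligner.
- Fisher's exact test on pooled counts ignores replicate-level
  overdispersion; calls are fold-change-driven by design and p-values are
  descriptive.
- Gene spans without padding can miss sites just downstream of annotated
  ends; supply extended models if that matters.
- The ambiguous-overlap rule removes every site in overlapping gene
  regions, which is conservative for genuinely nested genes.
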