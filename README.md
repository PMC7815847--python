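# ipaseq

Intronic polyadenylation (IpA) analysis from 3′-end sequencing.

Cleavage/polyadenylation inside an intron truncates a transcript before its
canonical 3′UTR, with real regulatory consequences — for example during
epithelial differentiation, where IpA usage shifts genome-wide and depends on
the CPSF complex. `ipaseq` implements the full computational path from raw
3′READS+-style reads to differential IpA calls, for method developers and
analysts who want each stage of that pipeline as a tested, reusable library:

1. **PASS reads** — trim the 4-nt UMI and the residual poly(A)-derived T
   tail (one embedded non-T allowed; inserts < 22 nt dropped), align
   (built-in exact aligner or external SAM/BAM, MAPQ ≥ 10), then rescue tail
   T's explained by genomic A's within 20 bp downstream of the cleavage
   site. Reads retaining ≥ 2 unmappable T's are Poly-A Site Supporting
   (PASS); fully rescued tails mark internal priming and are discarded.
2. **PolyA sites** — single-linkage clustering of PASS cleavage positions
   within 24 nt; exclusion-interval filters (blacklist, retrotransposons,
   miRNA, snoRNA); unique-gene assignment; robustness filters (host gene
   ≥ 5 RNA-seq counts in a condition, replicate sum ≥ 10, FPU ≥ 10% in a
   library); intron-priority annotation with single-site genes re-annotated
   as 3′UTR; removal of sites in overlapping gene spans.
3. **FPU statistics** — the fraction of polyA-site usage,
   FPU = c_s / Σ_{s′∈gene} c_{s′} per library, is internally normalized
   within each library and so comparable across conditions without depth
   scaling. Differential IpA requires FPU fold change ≥ 2, an RNA-seq
   ±100 bp window fold change ≥ 1.5 in the same direction, and more RNA-seq
   counts upstream than downstream of the site; knockdown dependence
   requires a same-direction fold change ≥ 1.5 in knockdown libraries.
   Tandem-3′UTR genes get a distal-usage index (distal-site count share)
   classifying 3′UTR lengthening/shortening at fold change 1.5.
4. **Synthetic data** — a generator plants a toy genome, three-exon gene
   models, polyA sites with per-condition usage fractions, AATAAA signals,
   internal-priming decoys over genomic A-runs, 3′READS+ FASTQ libraries
   and matched strand-specific RNA-seq positions, so every stage is scored
   against known ground truth with no downloads.

## Worked example

```python
from ipaseq import SimConfig
from ipaseq.pipeline import (run_synthetic_pipeline, match_sites_to_truth,
                             differential_call_evaluation, build_report)

config = SimConfig(n_genes=50, reads_per_library=10_000, seed=42)
result = run_synthetic_pipeline(config, rnaseq_depth=30_000)

report = build_report(result)
print("sites:", report["total_sites"], report["sites_by_category"])
metrics = match_sites_to_truth(result)
print(f"recovery: {metrics['recovery']:.3f}  precision: {metrics['precision']:.3f}")
ev = differential_call_evaluation(result)
print(f"differential IpA calls: {report['differential_ipa']['total']} "
      f"(down {report['differential_ipa']['down']}, up {report['differential_ipa']['up']})")
print(f"recall of planted shifts: {ev['recall']:.3f}  false calls: {ev['n_false_calls']}")
print("distal 3'UTR classes:", report["distal_usage_classes"])
```

prints

```
sites: 87 {'utr3': 73, 'intron': 14}
recovery: 1.000  precision: 1.000
differential IpA calls: 7 (down 3, up 4)
recall of planted shifts: 1.000  false calls: 0
distal 3'UTR classes: {'unchanged': 11, 'lengthened': 7, 'shortened': 5}
```

All 87 planted sites supported by ≥ 10 PASS reads are recovered at their
exact cleavage positions with no spurious sites (decoy reads are removed by
the internal-priming rule); the 7 intronic sites planted with 3× usage
shifts are all called with the planted direction, and tandem-3′UTR genes
classify according to their planted distal-usage shifts.

The same workflow is available from the shell:

```bash
ipaseq simulate --out world --seed 42 --n-genes 50 --reads-per-library 10000
ipaseq pass-reads --genome world/genome.fa --fastq world/reads_UD.1.fastq --out-bed pass_UD.1.bed
# ... one pass-reads call per library, then:
ipaseq call-sites --manifest pass_manifest.tsv --gtf world/models.gtf \
    --rnaseq UD=world/rnaseq_UD.tsv --rnaseq DF=world/rnaseq_DF.tsv --out sites.tsv
ipaseq diff-ipa --sites sites.tsv --cond-a UD --cond-b DF \
    --rnaseq UD=world/rnaseq_UD.tsv --rnaseq DF=world/rnaseq_DF.tsv --out calls.tsv
ipaseq distal-utr --sites sites.tsv --cond-a UD --cond-b DF --out distal.tsv
ipaseq report --sites sites.tsv --calls calls.tsv --distal distal.tsv --out summary.json
```

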