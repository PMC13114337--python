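# regarch

Stratified regulatory-architecture analysis around a marker gene, for
tumor-cohort studies that ask whether a single expression marker organizes
higher-order regulation. Given a cohort with survival endpoints, DNA
methylation (Illumina 450k-style beta values), bulk expression and protein
structure predictions, the package answers four linked questions:

1. **Where should the cohort be split?** An optimal marker cutpoint is found
   by scanning candidate thresholds for the split maximizing the absolute
   standardized log-rank statistic, with a permutation p-value that accounts
   for the scan.
2. **Do chromatin compartments differ between the strata?** Probe-level
   methylation is aggregated into 100-kb bins; robust per-sample scores,
   oriented against an external compartment-eigenvector reference, give
   per-sample A/B calls. Per bin, the open fractions per stratum are
   compared (Δp_open = p_open,high − p_open,low) with Fisher's exact test
   and Benjamini–Hochberg correction across bins; runs of ≥3 consecutive
   significant bins merge into blocks; gene sets are tested for enrichment
   in significant bins (SigBins) and blocks (SigBlocks) with Fisher's exact
   test and Haldane-corrected odds ratios.
3. **Does the marker's coexpression neighborhood rewire?** Genes are ranked
   by |r|, the absolute Pearson correlation with the anchor gene. For a
   cofactor panel, stratum-specific correlations are compared with Fisher's
   r-to-z test, z = (atanh r_high − atanh r_low) / √(1/(n_h−3) + 1/(n_l−3)),
   BH-corrected across the panel. Target-set concentration near the top of
   the ranking is scored with a preranked running-enrichment statistic (ES)
   against a random-gene-set permutation null.
4. **Does the marker's protein offer reproducible pockets?** Pocket
   predictions from several detection tools are unified by residue-set
   Jaccard overlap into consensus pockets (UPs), ranked by a composite of
   min–max-normalized per-tool metrics, and annotated with per-residue
   pLDDT confidence and mutation counts.

A first-class synthetic-data module generates seeded datasets with known
ground truth for every stage (latent A/B states with a controlled
between-stratum shift δ, stratum-specific anchor–cofactor correlations,
threshold hazard effects, jittered multi-tool pocket tables), so the whole
pipeline is testable end to end.

## Worked example

Run the full synthetic pipeline from one root seed:

```sh
regarch report --seed 42 --outdir out
cat out/report.txt
```

```
cutpoint   -0.0275263  max|z|  6.362     perm_p     0.001998
compartments  n_sig  13  pct_dir_pos  84.6154  median_dpopen  0.333333  n_blocks  0
enrich  SigBins  target_genes  OR  5.71019  q  5.4029e-06
rewire  n_cofactors  8  n_sig  2  ES  0.982086  nominal_p  0.000999001
pockets  n_UPs  3
```

Reading the numbers: the scan recovers a cutpoint near the generating
threshold of 0 with a highly significant permutation p; 13 of 200 bins
differ between strata at FDR < 0.05, 84.6% of them shifted toward the
open/A state in the marker-high stratum with a median Δp_open of 0.33; the
synthetic target genes, which the generator placed inside shifted bins, are
5.7-fold enriched among significant bins; two cofactors show significant
rewiring at this modest sample size (n = 60/stratum); the target set
dominates the top of the |r| ranking (ES = 0.98); and all three generated
pockets are recovered as four-tool consensus UPs.

Each stage is also available separately (`regarch simulate | cutpoint |
compartments | enrich | intersect-de | rewire | pockets`) on plain TSV/BED
inputs, and as library functions (`regarch.cutpoint.scan_cutpoint`,
`regarch.compartments.test_bins`, `regarch.rewiring.delta_r_test`,
`regarch.pockets.unify_pockets`, ...).

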