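# Methods

## Survival cutpoint scan

Candidate thresholds are the distinct marker values whose induced split
keeps the low-group fraction inside a quantile window, 10–90% by default
(the window prevents degenerate strata; narrower windows trade sensitivity
at extreme splits for stability). At each candidate the two-group log-rank
statistic is accumulated over distinct event times with the
simultaneous-risk-set convention for ties: O−E = Σ_j (d1_j − d_j n1_j/n_j)
and hypergeometric variance V = Σ_j d_j (n1_j/n_j)(1 − n1_j/n_j)(n_j −
d_j)/(n_j − 1); the selected cutpoint maximizes |z| = |O−E|/√V, ties
resolving to the smallest candidate value so the choice is independent of
input order. Significance is assessed by permuting marker values against
the fixed (time, event) pairs and recomputing the scan maximum — a
selection-adjusted, exact-in-distribution alternative to the
Contal–O'Quigley asymptotic supremum distribution used by some cutpoint
tools; this is a deliberate design choice, as the permutation null is
directly testable. The p-value uses the add-one convention
(1 + exceedances)/(n_perm + 1), so the smallest attainable value is
1/(n_perm + 1). Dichotomization labels a sample "high" iff marker >
cutpoint; ties go low.

## Methylation-derived A/B compartments

Probes are assigned to non-overlapping 100-kb bins (0-based half-open
coordinates throughout; BED dialect for interval files) and averaged per
(bin, sample), ignoring missing probe values; bins with fewer than
`min_probes` (default 3, to stabilize bin means) are dropped. Analysis is
restricted to bins covered by the external reference track.

Per-sample scores are −(x − median)/MAD over retained bins, so lower
methylation maps to a higher, more open score; samples with MAD = 0 yield
missing calls. A single global flip per chromosome aligns the cohort-mean
score with the reference eigenvector (negate if the Pearson correlation is
negative), which makes the pipeline agnostic to the true direction of the
methylation–openness link; globally inverting the input betas leaves the
oriented calls unchanged. A call is A iff the oriented score is strictly
positive; an exact zero is treated as missing.

Per bin, open fractions over non-missing calls are compared between strata
(Δp_open = p_open,high − p_open,low; the closed fraction is the
complement). The default test is Fisher's exact test on the 2×2 call table
— calls are binary, and the exact test needs no large-sample argument; a
pooled two-proportion z-test is available. q-values are BH across all
tested bins genome-wide; bins with an empty stratum are excluded from the
test and from the BH family. Blocks are maximal runs of ≥ `min_run`
(default 3) genomically adjacent significant bins; an untested or dropped
bin breaks adjacency, since "consecutive" is read as adjacent 100-kb bins.

### Known bias of per-sample binarization

Thresholding at the per-sample median fixes every sample's genome-wide
A-fraction at exactly 1/2. When compartment shifts are one-directional, the
marker-high stratum's true open fraction exceeds 1/2 by
(fraction of shifted bins) × δ, and the clamp redistributes that excess as
missed open calls spread over open bins. At the defaults of the synthetic
study (20% of 200 bins shifted by δ = 0.3) this attenuates per-bin Δp_open
by roughly 0.06–0.09; on a genome-scale bin count with a small shifted
fraction (order 10⁻²) the effect is negligible. Separately, conditioning on
BH significance at n = 60/stratum selects bins whose estimated |Δp_open|
exceeds ≈ 0.27–0.33 (the per-bin standard error is √(2p(1−p)/60) ≈ 0.09),
so the median Δp_open among *significant* shifted bins sits near 0.33
regardless of any true δ below 0.3 — a truncation-selection (winner's
curse) effect, not an estimator defect. Recovery of small shifts should
therefore be read from all shifted bins, or from cohorts large enough that
selection is mild.

## Locus enrichment and DE intersection

Genes map to every retained bin their body intersects (half-open overlap);
the enrichment universe is the mapped genes — using all genes would inflate
enrichment with untestable symbols. A gene "overlaps" if any of its bins is
significant (SigBins) or inside a block (SigBlocks); any-hit is the
conventional gene-level reduction. Odds ratios are cross-products with a
Haldane 0.5 correction when a cell is zero; p-values are two-sided Fisher
exact; BH is applied across the supplied set collection within each level.
For the neighborhood-composition contrast, a bin is consensus-A when more
than half its non-missing calls are A, a gene takes the majority label of
its bins (ties excluded at both levels), and the two cohorts' top-K
(default 500) ranked genes are compared on their A/B counts with Fisher's
exact test. DE tables intersect into quadrants with |log2FC| > 0.6 and
adjusted p < 0.05 per table; duplicate symbols keep the smallest adjusted p.

## Cofactor rewiring and preranked enrichment

Pearson correlations with the anchor are computed over all samples; the
anchor is excluded from its own ranking, zero-variance genes are dropped,
and |r|-ties break lexicographically for reproducibility. The rewiring test
uses Fisher's r-to-z with standard error √(1/(n_h−3) + 1/(n_l−3)) and
two-sided normal p-values; records with |r| = 1 in a stratum are flagged
degenerate (the transform diverges) and carry no p. BH runs across the
supplied cofactor panel.

The preranked statistic walks the ranking: members add |r|^w (default
w = 1; w = 0 gives the rank-only statistic, invariant to monotone
transforms of the ranking score) normalized by the member total,
non-members subtract 1/(N − n_set); ES is the signed maximum-magnitude
deviation, bounded by 1. Because the operation receives only a ranked list,
the null permutes gene-set membership (random same-size sets), not sample
labels; the nominal p uses the add-one convention. No numeric equivalence
with any external enrichment implementation's normalization is claimed.

## Pocket consensus

Predictions are linked when their residue-set Jaccard index reaches
`jaccard_min` (default 0.25); connected components spanning at least
`min_tools` distinct tools (default 2; a strict all-four-tools preset is a
matter of raising `min_tools`) become unified pockets. Residue identity is
the portable overlap proxy; 3-D distance overlap is deliberately not
implemented. Within a UP, a tool contributing several predictions is
summarized by its best value per metric. Prioritization min–max normalizes
every metric across UPs (missing → metric minimum; constant metrics
contribute 0.5), averages with configurable weights (equal by default — a
transparent, explicit invention; the underlying tools do not share a score
scale), and relabels UP1…UPk in descending composite order, ties broken by
residue count then residue content. pLDDT can be read from a residue-track
TSV or averaged per residue from a PDB temperature-factor column.

## Synthetic data

One root seed feeds fixed named substreams, so datasets are reproducible
individually and jointly. The methylation model draws per-bin base open
probabilities p_b ~ U(0.25, 0.75) on a single pseudo-chromosome; shifted
bins use min(p_b + δ, 0.98) in the high stratum. Betas come from truncated
normal components, N(0.3, σ) for open and N(0.7, σ) for closed states
(σ = 0.1) — a deliberately simple monotone state-to-methylation link that
makes the orientation step necessary; it is a stand-in, not an inference
about real 450k noise, and carries none of the probe-type, purity or
copy-number structure of real arrays. The reference value is the
population-mean openness centred at 0.5. Expression uses the linear
construction cof = r·anchor + √(1−r²)·ε per stratum, whose population
correlation is exactly r; defaults give two strata of 60 samples, an
eight-cofactor panel with four rewired members (Δr ≈ 0.45 against r_low ≈
0.1–0.2) and 50 target genes at r = 0.35. Survival times are exponential
with hazard 1/365 per day, multiplied by the hazard ratio (default 3) below
the marker threshold; censoring is uniform on (0, c) with c solved by
bisection so the expected censored fraction matches the requested rate
(default 0.3). Pocket fixtures emit every true pocket from every tool with
boundary jitter and decoys private to one tool in a low-confidence region,
disjoint across tools so they can never form cross-tool consensus; pLDDT is
85–98 inside true pockets.

Passing tests on these data demonstrate estimator correctness, calibration
and recovery under the generating model; they do not establish performance
on real cohorts, where probe quality, cellular composition, batch structure
and non-exponential hazards all intrude.

## Problem sizes and defaults

The test suite and acceptance script run at 200 bins × 5 probes ×
60 samples/stratum for compartments (250/stratum for rewiring recovery,
150/stratum for cutpoint recovery), 200-replicate null calibrations with
99 permutations each, and 1000-permutation single analyses — sizes at which
Monte-Carlo error is small relative to the assertions being made.
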