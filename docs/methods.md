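# Methods

This note documents the models and procedures implemented in `regshift`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Regulatory potential and in-silico deletion

**Model.** The regulatory potential of gene *g* on a depth-normalized
cut-count track is

    RP_g = Σ_b s(b) · 2^(−d(b)/δ),   d(b) ≤ W,

where the signal is summed into bins of `bin_size` (default 1 kb), `d(b)`
is the distance from the bin center to the gene's TSS, `δ` is the
half-decay distance (default 10 kb — the weight halves every 10 kb) and
`W` the window (default 100 kb). The weighting is TSS-anchored; signal
over the gene body carries no extra weight. Distance-decay RP models of
this family differ in whether and how they integrate over the gene body;
the TSS-only exponential form was chosen for transparency and exact
testability against a per-base brute-force oracle (`bin_size = 1`), with
which it agrees to < 1e-9 relative error.

**Deletion.** `insilico_delete` zeroes the signal at exactly the bases it
is given. The TF-level drivers (`isd_delta_rp`, `targeted_isd`) first
extend each site by a **500 bp deletion pad** per side. A motif span is
~15 bp; masking it alone removes well under 1% of any gene's RP no matter
how strong the site, so fractional-reduction thresholds like the 10%
disruption rule would be unreachable. The pad approximates removing the
sequencing fragments / peak region overlapping a bound site, which is the
operation a practitioner performs at track level; 500 bp matches the pad
used when intersecting dynamic binding sites with variants, keeping one
geometry throughout.

**Regulator ranking.** Per TF, a one-sided Mann-Whitney test compares
ΔRP of the DE genes against one seeded random sample of `n_background`
non-DE genes (shared across TFs so ranks are comparable; default 500,
reduced to 150 at the toy scale where only 200 genes exist). B-H FDR is
applied across TFs. A TF whose ΔRP is identically zero is assigned p = 1.

**Targeted ISD.** A gene is *disrupted* when its fractional RP reduction
strictly exceeds 10% (a reduction of exactly 10% does not count). The
empirical p uses the add-one estimator `(1 + #{null ≥ obs})/(N + 1)` over
`N = 1000` expression-matched background gene sets, so p is never 0 and
is conservative at ties.

**Expression matching** bins genes into deciles of mean expression (ties
broken by gene id for determinism); each background set reproduces the DE
set's per-decile composition, sampling without replacement within a set
and excluding the DE genes themselves. Because baseline expression is
log-normal, matching quality is assessed on the log scale: the arithmetic
mean of a 20-gene set is dominated by top-decile tail draws and is not a
stable matching summary, while geometric means of matched sets agree with
the DE set within a few percent.

## Differential footprinting

**Bias correction** divides the signal at each position by the expected
relative cut rate of the k-mer starting there (default k = 2) and
rescales to the original library size. This is an intentionally simple
stand-in for regression-based transposase bias models: the synthetic
generator plants exactly this form of bias (a fixed dinucleotide
multiplier table), closing the loop so correctness is testable — after
correction, mean signal at high- and low-bias positions in site-free
regions agrees within 5%. K-mers missing from the table get rate 1.0 with
a warning, never an error.

**Footprint score** = mean corrected signal in the two 30 bp flanks minus
mean within the motif span, clipped at 0 (bound motifs are protected from
transposition, so depletion against tall flanks indicates binding).
Clipping keeps fold changes defined for unbound sites at the cost of
breaking linearity at 0.

**Dynamic binding sites.** Δ = log2((s_t + ε)/(s_c + ε)) with pseudocount
ε = 0.01 on the depth-normalized score scale; a site is a DBS iff
|Δ| ≥ 1 ("two-fold" is interpreted on the ε-stabilized scores, since raw
scores of unbound sites are 0). Direction is *activated* for Δ > 0.
Swapping the condition labels negates every Δ exactly.

**Per-TF differential binding.** Scores of all sites of all TFs are
mapped to [0, 1] by a single min-max scale shared by both conditions, and
Δscore per TF is the mean scaled change over its sites. Scaling each
condition by its own extremes was considered and rejected: a condition's
minimum/maximum are order statistics that the differential sites
themselves shift (a site unbound in one condition scores ~0 there),
which leaks a spurious global offset of ~0.2 into every unchanged site
and cancels the true signal. With the shared scale, unchanged sites sit
at Δ = 0, label-swap antisymmetry is exact, and identical tracks give
Δ ≡ 0. Significance comes from `n_perm` size-matched random site draws
out of the pooled site universe (two-sided, add-one estimator), with B-H
FDR across TFs; the significance flag additionally requires
|Δscore| > 0.1. Note the permutation null tests "is this TF's site set
exchangeable with a random draw from the pool", which is the intended
question only when site sets are comparable; the |Δscore| threshold
guards against flagging TFs that merely mirror the pool's composition.

## Rank-rank hypergeometric overlap

Genes are ranked by `sign(logFC) · (−log10 p)`, descending, ties broken
by gene id; the caller must floor p = 0 upstream (the generator floors at
1e-300). For each threshold pair (i·step, j·step) the overlap of the two
top segments is tested with the exact hypergeometric upper tail; the grid
is B-H adjusted over all cells and reported as −log10 FDR. The default
step ⌊N/100⌋ caps the map at 100×100. Only the concordant one-sided map
is implemented: both lists descending, cell (0,0) = up-up corner. Under
this convention an exactly reversed list produces *depletion* everywhere
(for thresholds a, b as fractions, overlap a+b−1 is always below the
expectation ab), so anti-concordance shows as a non-significant map, not
as an anti-diagonal ridge — that ridge belongs to quadrant/two-sided RRHO
variants, which are out of scope.

The flat gene-set comparison is a one-sided (enrichment) Fisher exact
test returning the sample odds ratio.

## Variant prioritization

LD is computed from a user-supplied binary haplotype panel:
r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)). Filters are strict
inequalities (p < 5×10⁻⁸, MAF > 1%). Pruning is greedy by ascending p
(ties by rsid, making the result input-order invariant): a variant is
kept iff r² ≤ 0.1 with every kept variant on its chromosome. Pooling
attaches every same-chromosome variant with r² > 0.8 (strictly) to its
index; a proxy contested by two indexes goes to the lower-p index.
Variant tables carry 1-based positions; interval arithmetic is 0-based
half-open, converting on the way in and out. DBS intervals are extended
500 bp per side before intersection; a variant may match several
overlapping extended DBSs and then appears once per locus. Gene
annotation is by gene-body containment and labelled "intron" as a proxy —
exon structure is not modelled. Allelic imbalance uses the exact
two-sided binomial test against proportion 0.5.

## Synthetic data generator

The generator emulates the statistical structure the downstream stages
assume, at a desk scale where the full pipeline runs in seconds:

- **Genome**: 2 chromosomes × 1 Mb of uniform-random sequence.
- **Annotation**: 200 genes (5–30 kb bodies, strand-aware TSS), 5 TFs ×
  200 non-overlapping 15 bp sites. The first TF is the planted regulator:
  30% of its sites are "altered" and placed 0.5–3 kb from the TSSs of 20
  designated target genes (always within 50 kb). Sites keep 600 bp clear
  of chromosome ends so flanks and pads always fit.
- **Cut tracks**: per-base Poisson counts; rate = 0.2 cuts/bp background,
  raised to 2.0 within ±200 bp of each site center, multiplied by
  (1 − 0.8) inside bound motifs (the footprint), and modulated everywhere
  by a fixed dinucleotide bias table. Altered sites are bound in one
  condition only (treated, for an "activated" regulator). 4 replicates
  per condition. Poisson rather than negative-binomial noise: the
  downstream statistics are rank- and ratio-based, and replicate pooling
  is the only use of the replicate dimension.
- **Expression**: baseline log2 means ~ Normal(5, 2); the 20 target genes
  gain +2 log2FC in the treated condition; per-gene p from a two-sample
  t-test on 4 simulated log2 replicate values per condition (σ = 0.5).
  A second "plaque-like" signature correlates with the first at ρ = 0.7
  on the signed-significance scale. No donor/batch covariate structure is
  simulated.
- **Haplotypes/GWAS**: 2,000 variants, 500 haplotypes, LD blocks of 10
  consecutive variants built by copying one of two complementary founder
  patterns with 2% per-allele mutation (within-block r² ≈ 0.85,
  cross-block ≈ 0, MAF ≈ 0.5 by construction). Three causal loci: the
  causal variant is moved to the center of a distinct altered site, given
  p = 10^−U(9,14) and |β| ≈ 0.04; block-mates get r²-graded p; one
  exact-copy proxy (r² = 1) is planted per causal variant. Null variants
  have p ∈ [10⁻⁴, 1], so nothing else reaches genome-wide significance.

Randomness is one seed with fixed per-stage stream keys, so adding a
stage never perturbs earlier stages and every output is bit-reproducible.

**What passing tests do not show.** The generator has no fragment-length
mixture, nucleosome positioning, copy-number structure, overdispersion,
batch effects, population stratification or realistic motif content; its
bias model is the same family the corrector assumes. Recovery results
therefore validate the inference logic and its calibration, not
performance on real sequencing data, whose DBS and DE counts depend on
real depth and motif universes.

## Problem sizes and calibration checks

Default-scale recovery runs use 20 seeds (tests) or 10 seeds (summary
script). Null calibration of the targeted ISD uses a reduced scale
(1 × 400 kb chromosome, 150 genes, 2 TFs × 60 sites, 2 replicates,
99 null sets, 200 seeds) — the calibration property is scale-free, and a
12-site deletion keeps the disrupted-gene set a non-trivial fraction so
the statistic is non-degenerate. Because the add-one permutation p is
conservative exactly at ties, uniformity is checked on the randomized
tie-broken transform (uniform under exchangeability); the discrete exact
binomial p of the allelic-imbalance test is likewise checked against its
exact null atom distribution rather than a continuous uniform.

## Known limitations

- RP ignores the gene body and enhancer-promoter looping; genes on the
  same locus share signal.
- The bias corrector and the generator share the k-mer model family; real
  transposase bias needs a richer model.
- Per-TF differential binding assumes site sets of comparable score
  distributions (one pooled scale).
- Gene annotation of variants is body-containment only.
- LD pooling with many overlapping extended DBSs can assign one variant
  to several loci; locus counts are per-DBS, not per merged region.
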