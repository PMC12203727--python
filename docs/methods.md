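# Methods

## Problem and pipeline

`chromtrans` quantifies how chromatin-state transitions between cell types
distribute over gene sets relative to the genomic background. The pipeline
is: (1) interval preprocessing of peak/segmentation BED files, (2) genome
binning and gene-level transition counting along a differentiation order,
(3) a hierarchical beta-binomial fit to the count table, (4)
common-language effect sizes (CLES) per transition and cell pair.

## Interval conventions

All coordinates are 0-based half-open (BED). Interval sets are canonical:
sorted, with overlapping *and* touching intervals merged, so base-pair
arithmetic (intersection, union, Jaccard = intersection bp / union bp, with
0 for an empty union) has a unique representation. Strand is parsed but
ignored by all arithmetic. Chromosome filtering (e.g. excluding sex
chromosomes when sample sex is unknown) is an allow-list
(`IntervalSet.filter_chroms`); by default all chromosomes are kept.

Peak merging joins neighboring peaks whose gap is *strictly* less than
`max_gap_bins x bin_size` (default 3 bins; typical bin sizes are 200 bp for
narrow promoter marks and 800 bp for broad marks), transitively along the
chromosome; the operation is idempotent. Consensus peaks are the base-pair
intersection across replicates.

## Transition counting

The genome is tiled from position 0 in fixed bins (default 200 bp). Each
bin takes the state covering most of its base pairs; uncovered base pairs
count toward the designated empty state; ties break toward the state listed
first in the configured alphabet. Segmentations produced by HMM segmenters
are bin-aligned in practice, so the majority rule only matters for foreign
inputs.

Sample pairs follow the differentiation order: for cell types u before v,
all replicate combinations are emitted u→v; within a cell type each
unordered replicate pair appears once, its direction drawn from a seeded
RNG because replicates have no intrinsic order. For n cell types and K
states this yields n(n+1)/2 cell pairs and n(n+1)/2 x K² transition
categories (e.g. 1350 for 3 cell types and 15 states).

A gene carries transition (x, y) for a sample pair iff at least one bin
overlapping its body (annotation start–end, no flanks) has state x in the
origin and y in the target sample; self-pairs (x, x) are valid transitions.
Genes overlapping no tiled bin carry the empty-state self-transition.
Overlapping genes each receive a bin's transition independently. Counts are
tallied per (gene set, transition, cell pair, replicate pair), and
zero-count rows are kept so the model sees never-observed transitions. The
vectorized path is tested for exact equality against a naive per-gene,
per-base-pair enumeration oracle on random fixtures.

`occurrence_rate` reports, per gene, in how many (replicate pair,
transition) combinations the gene shows any of a pooled list of
transitions, along with the theoretical maximum computed from first
principles as (#replicate pairs across the listed cell pairs) x (#listed
transitions) — e.g. 12 for a (2,3)-replicate cell pair with two pooled
transitions.

## The hierarchical beta-binomial model

Observed counts per replicate pair are beta-binomial; see the README for
the full specification. Key modeling choices:

- **One joint fit per gene set.** All (t, d) cells of the set *and* the
  background share the two exponential hyper rates α_h, β_h, so weakly
  observed cells shrink toward the pooled behavior. Background shapes are
  refit within each gene-set model because the hierarchy ties them to the
  same hyperprior.
- **Hyperpriors** are Exponential(10) (parameter `hyper_rate`), preferring
  small rates and hence broad, weakly informative shape priors.
- **Within-cell-type pairs** (e.g. MSC→MSC) enter the same fit as ordinary
  d levels; they measure within-type decoration dynamics and share the
  hierarchy.

## Posterior sampling

No gradient-based probabilistic-programming sampler is used; the posterior
has exploitable structure and is sampled by a Gibbs-within-Metropolis
scheme authored in the package:

- Each of the 2C shape pairs (C cells x {set, background}) is
  reparameterized as (logit p, log ν) with α = pν, β = (1−p)ν — the mean /
  precision split decorrelates the two coordinates — and updated by
  coordinate-wise Gaussian random-walk Metropolis, vectorized across all
  units (the units are conditionally independent given the hypers).
  Proposal scales adapt per unit and coordinate during warmup toward ~35%
  acceptance.
- Given all shapes, the hyper rates are conjugate:
  α_h | · ~ Gamma(2C + 1, hyper_rate + Σα), and likewise β_h; they are
  drawn exactly (Gibbs).
- One joint multiplicative move per iteration rescales all α (and,
  separately, all β) by a common log-normal factor. The shared rates couple
  the shapes, and cells with no observed transitions leave the common scale
  only weakly identified, so coordinate-wise walks cross this direction
  slowly; the joint move roughly doubles the hyper-rate effective sample
  size at negligible cost. (An interweaving variant that co-moves the hyper
  rate was tried and performed worse; the plain multiplicative move is
  kept.)

Defaults: 4 chains, 1000 warmup iterations, 1000 retained draws per chain
with thinning 5 (i.e. 5000 post-warmup iterations), seeded per chain from a
`SeedSequence` spawn so fits are exactly reproducible. Convergence is
summarized by rank-normalized split-R-hat (via arviz) over every shape
parameter and the hypers; fits with max R-hat > 1.05 emit a warning and set
`converged_ = False` — the threshold follows standard MCMC practice. Tables
with a small background and many zero cells mix more slowly; raising `thin`
to 10–15 brings such fits under the threshold (the README example uses 15).

**Validation.** The sampler is checked in the test suite against two
independent references: (a) with frozen hyper rates a single cell's
posterior is a 2-D integral, evaluated by trapezoid quadrature on a
(p, log ν) grid; (b) the full joint posterior of a one-cell model
(6 dimensions, hyper sampling included) is sampled by the affine-invariant
ensemble sampler `emcee` from an independently written log-density.
Posterior means of the transition proportions agree with both. Calibration
is checked by interval coverage over repeated simulations from the
generative model.

## Effect sizes

inc, dec and CLES are evaluated per posterior draw and summarized by the
posterior mean (the reported single-value effect size) plus a central 95%
interval of CLES. The posterior mean of the per-draw CLES is used rather
than CLES at the posterior-mean shapes; the difference between the two
(Jensen gap) is reported as a diagnostic column and is small in practice.
The group-size-N CLES draws on the exact pmfs of BetaBin(N, α^g, β^g) and
BetaBin(N, α^a, β^a): P(X_g > X_a) + ½P(X_g = X_a), with ties given weight
½ by the standard common-language convention; it is deterministic given the
draws, reduces algebraically to the single-gene CLES at N = 1, and its
ranks track the N = 1 ranks closely on synthetic grids.

## Posterior predictive checks

For each observed count the expected count is the posterior mean of
n·α/(α+β) for the row's cell and group; the PPC table reports each
observation against this expectation and the mean difference per (t, d,
group). Under well-specified data the differences center near zero; single
extreme replicate observations are deliberately not chased — the hierarchy
shrinks them, producing a visible (and expected) residual.

## Synthetic data generator

`simulate_segmentations` emulates the structure of multi-replicate ChromHMM
segmentations without emulating ChIP-seq signal: a toy genome (default one
2-Mbp chromosome, 500 non-overlapping genes of ~2 kbp ± 0.4 kbp, 200-bp
bins — small enough that counting + fitting + effect sizes run in minutes
on one CPU), a first-cell-type consensus with i.i.d. per-bin states (the
empty state weighted as heavily as all decorated states combined), a
per-bin redraw probability (default 0.05) between consecutive cell types,
planted gene sets whose gene-body bins are overwritten with a designated
transition between a designated cell pair with a per-gene probability, and
independent per-replicate bin-flip noise (default 0). The truth table
records exactly which genes were planted. Features of real data *not*
emulated: spatially correlated state runs, distance decay around
promoters/gene bodies, replicate-specific biases, and realistic state
frequencies — so passing tests demonstrate correctness of counting and
inference, not robustness to every real-data pathology.

`simulate_counts` bypasses segmentations and draws count rows directly from
the generative beta-binomial model via the Beta-then-Binomial construction,
parameterized by proportions and a precision ν (α = pν, β = (1−p)ν); large
ν approaches the plain binomial. The null-calibration grid used by
`scripts/acceptance.py` (5 states, 2 cell types, 6 replicate pairs,
p = 0.05 for set and background, ν = 50, S = 100, A = 20000) is drawn this
way; under it the average posterior-mean CLES sits at 0.5 and per-cell
values stay within a few hundredths of it.

## Degenerate inputs and numerical notes

- All-zero counts: posterior proportions concentrate near 0 for both set
  and background; CLES ≈ 0.5.
- Likelihoods are evaluated in log space via `scipy.special.betaln`; the
  binomial coefficient, constant in the parameters, is omitted inside the
  sampler and included in the exposed pmf.
- Degenerate simulation probabilities p = 0 / p = 1 short-circuit to
  constant counts (the Beta draw would be undefined).
- Empty count tables, single-chain R-hat requests, non-positive set sizes,
  and multi-set tables passed to a single fit all raise informative errors.

## Known limitations

- The sampler's random-walk core needs longer runs on tables whose
  background is small or whose counts are mostly zero; convergence is
  flagged, not silently accepted.
- Transition calling is bin-resolution; sub-bin boundary effects are
  resolved by the majority rule and ties by alphabet order.
- Gene bodies are used without flanks; promoter-flank decoration attributed
  to a neighboring gene's body is counted for that neighbor.
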