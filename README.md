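# chromtrans

Chromatin-state transition enrichment analysis along a differentiation
trajectory.

Cell differentiation leaves tracks in the epigenome: histone-modification
combinations ("chromatin states", as segmented per sample by tools like
ChromHMM) change at some genes as one cell type matures into the next. The
genes that matter for a lineage are few, so their transitions are easily
drowned out by genome-wide drift and by technical differences between
datasets. `chromtrans` addresses this with a *relative* analysis: it counts,
for every ordered pair of chromatin states and every ordered pair of cell
types along the differentiation order, how many genes of a chosen gene set
carry that transition — and contrasts those counts against the background of
all genes using a Bayesian hierarchical model. It is aimed at computational
epigenomics users who have per-replicate segmentation BED files, a gene
annotation, and gene sets of interest.

## The model

For gene set *g* with *S* genes and a background of *A* genes, the number of
genes carrying transition *t* (ordered state pair) at differentiation step
*d* (ordered cell-type pair, including within-type replicate comparisons),
observed once per replicate pair *(i, j)*, is modeled as beta-binomial to
capture between-replicate overdispersion:

    s_{t,d,i,j} ~ BetaBin(S, α^g_{t,d}, β^g_{t,d})
    a_{t,d,i,j} ~ BetaBin(A, α^a_{t,d}, β^a_{t,d})
    α^g, α^a ~ Exponential(α_h)      β^g, β^a ~ Exponential(β_h)
    α_h, β_h ~ Exponential(10)

All (t, d) cells of the set and the background are fit jointly, sharing the
two hyper rates. Effect sizes come from the posterior: with transition
proportions p = α/(α+β),

    inc = (1 − p_a) · p_g        (set gene transitions, background gene does not)
    dec = p_a · (1 − p_g)        (the reverse)
    CLES = (inc + (1 − dec)) / 2

The common-language effect size CLES compares one representative set gene
with one representative background gene: 0.5 means no enrichment, values
above 0.5 enrichment of the transition in the set, below 0.5 depletion. It
is evaluated per posterior draw and summarized by its mean and central 95%
interval. A group-size-N variant (`cles_group`) compares counts among N
genes per side, computed exactly from the two beta-binomial pmfs.

The posterior is sampled by an in-package Gibbs-within-Metropolis scheme:
conjugate Gamma updates for the hyper rates, adaptive random-walk updates of
each cell's (logit mean, log precision), and joint multiplicative moves
along the shape/hyper-coupled direction. Convergence is monitored by
rank-normalized split-R-hat (threshold 1.05) and posterior predictive
checks. See `docs/methods.md` for details and validation.

## Worked example

Simulate a small two-cell-type experiment in which 12 "chondro" genes gain
the repressive-active promoter state (losing activating-only promoter
decoration) from MSC to hypertrophic chondrocytes, count transitions, fit,
and rank effect sizes:

```python
from chromtrans import (
    PlantedSet, SyntheticSpec, TransitionEnrichmentModel,
    build_transition_table, cles_posterior, simulate_segmentations,
)

planted_genes = tuple(f"gene{i:04d}" for i in range(12))
spec = SyntheticSpec(
    n_genes=150, genome_length=500_000,
    cell_types=("MSC", "HC"), replicates_per_type=(3, 3), noise=0.02,
    planted_sets={"chondro": PlantedSet(
        gene_ids=planted_genes, state_from="ActProm", state_to="RepActPro",
        cell_from="MSC", cell_to="HC", prob=0.8)},
    seed=4,
)
segs, genes, truth = simulate_segmentations(spec)
print(f"{len(segs)} samples, {len(genes)} genes, {len(truth)} planted transitions")

table = build_transition_table(
    segs, spec.order(), genes, {"chondro": list(planted_genes)},
    spec.bin_size, spec.state_labels, spec.empty_state, rng_seed=0)
est = TransitionEnrichmentModel(chains=4, draws=1000, warmup=1000, thin=15, seed=0).fit(table)
print(f"max split-R-hat: {est.max_rhat_:.3f}")

effects = cles_posterior(est.posterior_)
top = effects.sort_values("cles_mean", ascending=False).head(3)
cols = ["state_from", "state_to", "cell_from", "cell_to",
        "cles_mean", "cles_ci_low", "cles_ci_high"]
print(top[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
```

Output:

```
6 samples, 146 genes, 8 planted transitions
max split-R-hat: 1.046
state_from  state_to cell_from cell_to  cles_mean  cles_ci_low  cles_ci_high
   ActProm RepActPro       MSC      HC      0.793        0.747         0.837
   ActProm   ActProm       MSC     MSC      0.583        0.520         0.630
 RepActPro RepActPro        HC      HC      0.568        0.505         0.614
```

The planted ActProm→RepActPro transition from MSC to HC ranks first with a
strong enrichment (CLES 0.79, well above the 0.5 no-effect point); the
runner-up entries are within-cell-type self-transitions near 0.5–0.6, the
level of background fluctuation. Only 8 of the 12 planted genes actually
received the transition (planting probability 0.8), which the `truth` table
records.

The same workflow is available from the shell:

```sh
chromtrans simulate spec.yaml -o bundle/
chromtrans count -c bundle/config.yaml -o counts.tsv
chromtrans fit --counts counts.tsv -o results/
chromtrans jaccard a.bed b.bed -o jaccard.tsv
chromtrans coverage -c bundle/config.yaml -o coverage.tsv
```

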