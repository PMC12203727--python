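"""Genome binning, sample-pair enumeration, and gene-level transition counting.

The genome is tiled from position 0 into fixed-size bins. For an ordered pair
of samples (origin, target) taken along the differentiation order, each bin
carries a state transition (origin state, target state); a gene carries a
transition type if at least one bin overlapping its body shows it. Counting
how many genes of a set versus the background carry each transition type, per
replicate pair, yields the observation table the hierarchical model is fit to.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, Segmentation

__all__ = [
    "DifferentiationOrder",
    "SamplePair",
    "binned_states",
    "enumerate_sample_pairs",
    "gene_transition_indicator",
    "count_transitions",
    "build_transition_table",
    "transition_category_count",
    "occurrence_rate",
]

COUNT_COLUMNS = [
    "gene_set",
    "cell_from",
    "cell_to",
    "rep_from",
    "rep_to",
    "state_from",
    "state_to",
    "s",
    "S",
    "a",
    "A",
]


@dataclass(frozen=True)
class DifferentiationOrder:
    """Ordered cell types and their replicate ids.

    ``cell_types`` lists cell types from least to most differentiated;
    transitions are only counted in this direction (and within a cell type).
    """

    cell_types: tuple[str, ...]
    replicates: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell types must be unique")
        for ct in self.cell_types:
            if ct not in self.replicates or len(self.replicates[ct]) == 0:
                raise ValueError(f"cell type {ct!r} needs at least one replicate")

    def n_cell_pairs(self) -> int:
        n = len(self.cell_types)
        return n * (n + 1) // 2


@dataclass(frozen=True)
class SamplePair:
    """An ordered (origin, target) pair of samples.

    Between cell types the origin precedes the target in the differentiation
    order; within a cell type each unordered replicate pair appears once with
    a randomly assigned direction.
    """

    cell_from: str
    cell_to: str
    rep_from: str
    rep_to: str

    @property
    def within_type(self) -> bool:
        return self.cell_from == self.cell_to


def enumerate_sample_pairs(order: DifferentiationOrder, rng_seed: int = 0) -> list[SamplePair]:
    """All sample pairs respecting the differentiation direction.

    For cell types u preceding v, every (replicate of u, replicate of v)
    combination is emitted. Within a cell type each unordered replicate pair
    is emitted exactly once; its direction is drawn from a seeded RNG, since
    replicates of one cell type have no intrinsic order.
    """
    rng = np.random.default_rng(rng_seed)
    pairs: list[SamplePair] = []
    cts = order.cell_types
    for a_idx, u in enumerate(cts):
        reps_u = order.replicates[u]
        # within-type pairs
        for r1, r2 in itertools.combinations(reps_u, 2):
            if rng.random() < 0.5:
                r1, r2 = r2, r1
            pairs.append(SamplePair(u, u, r1, r2))
        # between-type pairs, u before v
        for v in cts[a_idx + 1 :]:
            for r1 in reps_u:
                for r2 in order.replicates[v]:
                    pairs.append(SamplePair(u, v, r1, r2))
    return pairs


def transition_category_count(n_cell_types: int, n_states: int) -> int:
    """Number of unique (cell pair, state pair) transition categories.

    Cell pairs respect the differentiation order and include within-type
    pairs: n(n+1)/2 of them; each combines with every ordered state pair.
    """
    if n_cell_types < 1 or n_states < 1:
        raise ValueError("counts must be >= 1")
    return (n_cell_types * (n_cell_types + 1) // 2) * n_states**2


def binned_states(
    seg: Segmentation,
    bin_size: int,
    states: Sequence[str],
    empty_state: str,
    chrom_bins: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Tile each chromosome into fixed bins and label them with states.

    Returns, per chromosome, an int array of state codes (indices into
    ``states``). A bin straddling segments takes the state covering most of
    its base pairs; uncovered base pairs count toward ``empty_state``; ties
    break toward the state listed first in ``states``.

    ``chrom_bins`` fixes the number of bins per chromosome (so several
    samples are binned identically); by default it is derived from the
    segmentation's own extent.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    states = list(states)
    if empty_state not in states:
        raise ValueError("empty_state must be part of the state alphabet")
    seg.validate_states(states)
    code = {s: i for i, s in enumerate(states)}
    empty_code = code[empty_state]

    if chrom_bins is None:
        chrom_bins = {
            chrom: -(-int(end) // bin_size) for chrom, end in seg.chrom_extent().items()
        }

    out: dict[str, np.ndarray] = {}
    grouped = dict(tuple(seg.segments.groupby("chrom", sort=False)))
    for chrom, n_bins in chrom_bins.items():
        cov = np.zeros((n_bins, len(states)))
        if chrom in grouped:
            grp = grouped[chrom]
            for start, end, state in zip(
                grp["start"].to_numpy(), grp["end"].to_numpy(), grp["state"].to_numpy()
            ):
                end = min(int(end), n_bins * bin_size)
                start = int(start)
                if start >= end:
                    continue
                b0, b1 = start // bin_size, (end - 1) // bin_size
                ci = code[state]
                if b0 == b1:
                    cov[b0, ci] += end - start
                else:
                    cov[b0, ci] += (b0 + 1) * bin_size - start
                    cov[b1, ci] += end - b1 * bin_size
                    if b1 > b0 + 1:
                        cov[b0 + 1 : b1, ci] += bin_size
        covered = cov.sum(axis=1)
        cov[:, empty_code] += bin_size - covered
        out[chrom] = cov.argmax(axis=1).astype(np.int32)
    return out


def gene_transition_indicator(
    bins_from: Mapping[str, np.ndarray],
    bins_to: Mapping[str, np.ndarray],
    genes: GeneAnnotation,
    bin_size: int,
    n_states: int,
    empty_code: int,
) -> np.ndarray:
    """Boolean gene x transition-type matrix for one sample pair.

    Entry (g, x * n_states + y) is True iff some bin overlapping gene g's
    body has state code x in the origin sample and y in the target sample.
    Genes on chromosomes without bins (or overlapping no tiled bin) carry
    only the empty-state self-transition.
    """
    n_genes = len(genes)
    ind = np.zeros((n_genes, n_states * n_states), dtype=bool)
    empty_pair = empty_code * n_states + empty_code
    tab = genes.table
    for gi, (chrom, start, end) in enumerate(
        zip(tab["chrom"].to_numpy(), tab["start"].to_numpy(), tab["end"].to_numpy())
    ):
        bf = bins_from.get(chrom)
        bt = bins_to.get(chrom)
        if bf is None or bt is None or bf.size == 0:
            ind[gi, empty_pair] = True
            continue
        b0 = int(start) // bin_size
        b1 = min((int(end) - 1) // bin_size, bf.size - 1)
        if b0 > b1:
            ind[gi, empty_pair] = True
            continue
        codes = bf[b0 : b1 + 1].astype(np.int64) * n_states + bt[b0 : b1 + 1]
        ind[gi, np.unique(codes)] = True
        if int(end) > bf.size * bin_size:
            # gene extends past the tiled region: the untiled tail is empty
            ind[gi, empty_pair] = True
    return ind


def count_transitions(
    indicator: np.ndarray,
    genes: GeneAnnotation,
    gene_sets: Mapping[str, Sequence[str]],
    states: Sequence[str],
    pair: SamplePair,
) -> pd.DataFrame:
    """Gene counts per transition type for each gene set and the background.

    ``indicator`` is the matrix from :func:`gene_transition_indicator` for
    one sample pair. Rows are emitted for every (state_from, state_to) pair,
    including zero-count ones, so the model sees never-observed transitions.
    """
    states = list(states)
    n_states = len(states)
    gene_index = {g: i for i, g in enumerate(genes.gene_ids)}
    bg_counts = indicator.sum(axis=0)
    A = len(genes)
    frames = []
    sf = np.repeat(states, n_states)
    st = np.tile(states, n_states)
    for set_id, members in gene_sets.items():
        idx = [gene_index[g] for g in members if g in gene_index]
        s_counts = indicator[idx].sum(axis=0) if idx else np.zeros(n_states**2, dtype=int)
        frames.append(
            pd.DataFrame(
                {
                    "gene_set": set_id,
                    "cell_from": pair.cell_from,
                    "cell_to": pair.cell_to,
                    "rep_from": pair.rep_from,
                    "rep_to": pair.rep_to,
                    "state_from": sf,
                    "state_to": st,
                    "s": s_counts.astype(int),
                    "S": len(idx),
                    "a": bg_counts.astype(int),
                    "A": A,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]


def build_transition_table(
    segmentations: Sequence[Segmentation],
    order: DifferentiationOrder,
    genes: GeneAnnotation,
    gene_sets: Mapping[str, Sequence[str]],
    bin_size: int,
    states: Sequence[str],
    empty_state: str,
    rng_seed: int = 0,
    return_indicators: bool = False,
):
    """Full transition count table over all sample pairs.

    Bins all samples on a common tiling (the maximum covered extent across
    samples per chromosome), enumerates sample pairs along the
    differentiation order, and concatenates per-pair gene counts.
    """
    states = list(states)
    by_key = {(s.cell_type, s.replicate): s for s in segmentations}
    chrom_bins: dict[str, int] = {}
    for seg in segmentations:
        for chrom, end in seg.chrom_extent().items():
            n = -(-int(end) // bin_size)
            chrom_bins[chrom] = max(chrom_bins.get(chrom, 0), n)
    for chrom in set(genes.table["chrom"]):
        chrom_bins.setdefault(chrom, 0)

    binned = {
        key: binned_states(seg, bin_size, states, empty_state, chrom_bins)
        for key, seg in by_key.items()
    }
    pairs = enumerate_sample_pairs(order, rng_seed)
    empty_code = states.index(empty_state)
    tables = []
    indicators: dict[SamplePair, np.ndarray] = {}
    for pair in pairs:
        key_from = (pair.cell_from, pair.rep_from)
        key_to = (pair.cell_to, pair.rep_to)
        if key_from not in binned or key_to not in binned:
            raise ValueError(f"no segmentation for sample pair {pair}")
        ind = gene_transition_indicator(
            binned[key_from], binned[key_to], genes, bin_size, len(states), empty_code
        )
        indicators[pair] = ind
        tables.append(count_transitions(ind, genes, gene_sets, states, pair))
    table = pd.concat(tables, ignore_index=True)
    if return_indicators:
        return table, indicators
    return table


def occurrence_rate(
    indicators: Mapping[SamplePair, np.ndarray],
    genes: GeneAnnotation,
    gene_set: Sequence[str],
    transitions: Sequence[tuple[str, str]],
    cell_pairs: Sequence[tuple[str, str]],
    states: Sequence[str],
) -> tuple[pd.Series, int]:
    """Per-gene occurrence counts of pooled transitions across replicate pairs.

    For each gene in the set, counts the number of (replicate pair,
    transition) combinations — restricted to the listed cell pairs and
    transition types — in which the gene shows the transition. Also returns
    the theoretical maximum: (#replicate pairs across the listed cell pairs)
    x (#listed transitions).
    """
    states = list(states)
    n_states = len(states)
    code = {s: i for i, s in enumerate(states)}
    t_codes = [code[x] * n_states + code[y] for x, y in transitions]
    wanted = set(cell_pairs)
    gene_index = {g: i for i, g in enumerate(genes.gene_ids)}
    members = [g for g in gene_set if g in gene_index]
    idx = [gene_index[g] for g in members]
    counts = np.zeros(len(members), dtype=int)
    n_pairs = 0
    for pair, ind in indicators.items():
        if (pair.cell_from, pair.cell_to) not in wanted:
            continue
        n_pairs += 1
        counts += ind[np.ix_(idx, t_codes)].sum(axis=1)
    maximum = n_pairs * len(transitions)
    return pd.Series(counts, index=members, name="occurrences"), maximum
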