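"""Peak preprocessing and descriptive state-coverage statistics.

Covers the steps upstream and alongside the transition model: merging of
nearby peak calls, consensus (base-pair intersection) across replicates,
chromatin-state coverage of gene sets relative to the all-genes background,
state-pair Jaccard matrices between two segmentations, and gene-set
bookkeeping (length summaries, removal of genes shared between sets).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, IntervalSet, Segmentation, jaccard

__all__ = [
    "merge_nearby_peaks",
    "consensus",
    "state_coverage_on_genes",
    "relative_coverage_line",
    "state_pair_jaccard",
    "gene_length_summary",
    "remove_shared_genes",
]


def merge_nearby_peaks(peaks: IntervalSet, bin_size: int, max_gap_bins: int = 3) -> IntervalSet:
    """Merge neighboring peaks separated by less than ``max_gap_bins`` bins.

    Two peaks whose gap is strictly smaller than ``max_gap_bins * bin_size``
    base pairs are joined; merging is transitive along a chromosome. With
    ``max_gap_bins=0`` only touching/overlapping peaks merge (the normalized
    representation is returned unchanged).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if max_gap_bins < 0:
        raise ValueError("max_gap_bins must be >= 0")
    max_gap = max_gap_bins * bin_size
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in peaks.chroms:
        starts, ends = peaks.arrays(chrom)
        gaps = starts[1:] - ends[:-1]
        new_run = np.empty(starts.size, dtype=bool)
        new_run[0] = True
        new_run[1:] = gaps >= max_gap  # gap < max_gap merges (strict inequality)
        idx = np.flatnonzero(new_run)
        merged_starts = starts[idx]
        merged_ends = np.append(ends[idx[1:] - 1], ends[-1])
        out[chrom] = (merged_starts, merged_ends)
    return IntervalSet.from_arrays(out)


def consensus(replicate_peaks: Sequence[IntervalSet]) -> IntervalSet:
    """Base-pair-wise intersection of replicate peak sets."""
    if len(replicate_peaks) == 0:
        raise ValueError("consensus requires at least one replicate")
    result = replicate_peaks[0]
    for other in replicate_peaks[1:]:
        result = result.intersect(other)
    return result


def state_coverage_on_genes(
    seg: Segmentation,
    genes: GeneAnnotation,
    gene_set: Sequence[str],
    gene_set_id: str = "set",
) -> pd.DataFrame:
    """Per-state coverage (bp) on a gene set and on the all-genes background.

    The gene set is taken as the union of its gene bodies, so overlapping
    genes are not double-counted. Unresolvable ids are reported in the
    ``unresolved`` frame attribute, not fatal. Returns one row per state with
    columns (state, gene_set, cell_type, replicate, coverage_bp,
    background_bp).
    """
    found, missing = genes.resolve(gene_set)
    set_region = genes.body_intervals(found)
    bg_region = genes.body_intervals()
    rows = []
    for state in seg.states:
        regions = seg.state_regions(state)
        rows.append(
            {
                "state": state,
                "gene_set": gene_set_id,
                "cell_type": seg.cell_type,
                "replicate": seg.replicate,
                "coverage_bp": regions.intersect(set_region).total_bp(),
                "background_bp": regions.intersect(bg_region).total_bp(),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["state", "gene_set", "cell_type", "replicate", "coverage_bp", "background_bp"],
    )
    out.attrs["unresolved"] = list(missing)
    return out


def relative_coverage_line(set_genes_bp: int, all_genes_bp: int) -> float:
    """Slope of the equal-proportion reference line in coverage scatter plots.

    A state whose (set coverage, background coverage) point falls below the
    line ``y = slope * x`` is enriched on the set; above it, depleted.
    """
    if set_genes_bp <= 0:
        raise ValueError("gene-set total length must be positive")
    return all_genes_bp / set_genes_bp


def state_pair_jaccard(
    seg_a: Segmentation,
    seg_b: Segmentation,
    states_a: Sequence[str] | None = None,
    states_b: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Jaccard index of every state-pair's regions between two segmentations.

    Entry (x, y) compares the regions labeled ``x`` in ``seg_a`` with the
    regions labeled ``y`` in ``seg_b``. Because a segmentation partitions the
    covered genome, comparing a segmentation to itself yields 1 on the
    diagonal (for non-empty states) and 0 elsewhere.
    """
    states_a = list(states_a) if states_a is not None else seg_a.states
    states_b = list(states_b) if states_b is not None else seg_b.states
    regions_a = {s: seg_a.state_regions(s) for s in states_a}
    regions_b = {s: seg_b.state_regions(s) for s in states_b}
    mat = np.zeros((len(states_a), len(states_b)))
    for i, sa in enumerate(states_a):
        for j, sb in enumerate(states_b):
            mat[i, j] = jaccard(regions_a[sa], regions_b[sb])
    return pd.DataFrame(mat, index=states_a, columns=states_b)


def gene_length_summary(genes: GeneAnnotation, gene_set: Sequence[str]) -> pd.DataFrame:
    """Five-number summary of gene lengths for a set and the background."""
    found, _ = genes.resolve(gene_set)
    quantiles = [0.0, 0.25, 0.5, 0.75, 1.0]
    names = ["min", "q25", "median", "q75", "max"]
    set_lengths = genes.subset(found).lengths()
    bg_lengths = genes.lengths()
    rows = {
        "set": [float(set_lengths.quantile(q)) for q in quantiles] if len(set_lengths) else [np.nan] * 5,
        "background": [float(bg_lengths.quantile(q)) for q in quantiles],
    }
    return pd.DataFrame(rows, index=names).T


def remove_shared_genes(
    set_a: Sequence[str], set_b: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Drop genes present in both sets from each, preserving order.

    Used to make two tissue-specific sets disjoint before counting, so a
    gene cannot contribute to both enrichment contrasts.
    """
    shared = set(set_a) & set(set_b)
    return [g for g in set_a if g not in shared], [g for g in set_b if g not in shared]
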