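import numpy as np
import pandas as pd
import pytest

from chromtrans import GeneAnnotation, Segmentation


@pytest.fixture
def toy_genes() -> GeneAnnotation:
    """Five genes on a small two-chromosome toy genome."""
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4", "g5"],
                "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
                "start": [0, 1000, 2500, 0, 900],
                "end": [600, 2200, 3100, 800, 1500],
                "strand": ["+", "-", "+", "+", "-"],
            }
        )
    )


def make_segmentation(chrom_states, bin_size=200, **meta) -> Segmentation:
    """Build a bin-aligned segmentation from per-chrom state-label lists."""
    rows = []
    for chrom, labels in chrom_states.items():
        for i, lab in enumerate(labels):
            rows.append((chrom, i * bin_size, (i + 1) * bin_size, lab))
    return Segmentation(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]), **meta)


def brute_force_counts(per_bp_states, genes, gene_sets, states, bin_size, empty_state):
    """Naive gene x bin transition counting oracle.

    ``per_bp_states`` maps each sample key to {chrom: per-base-pair state
    label array}; bins are resolved by counting base pairs per state within
    the bin (ties to the state listed first in ``states``), genes collect
    the transition of every overlapping bin, and counts are tallied by a
    double loop. Independent of the package's vectorized path.
    """

    def bin_label(bp, b):
        lo, hi = b * bin_size, (b + 1) * bin_size
        chunk = bp[lo:hi] if lo < len(bp) else []
        tallies = {s: 0 for s in states}
        for lab in chunk:
            tallies[lab] += 1
        tallies[empty_state] += bin_size - len(chunk)
        best = max(tallies.values())
        for s in states:  # first state in configured order wins ties
            if tallies[s] == best:
                return s
        raise AssertionError

    def gene_transitions(bp_from, bp_to, chrom, start, end, n_bins):
        found = set()
        b0, b1 = start // bin_size, (end - 1) // bin_size
        if chrom not in bp_from or n_bins.get(chrom, 0) == 0 or b0 >= n_bins[chrom]:
            return {(empty_state, empty_state)}
        for b in range(b0, min(b1, n_bins[chrom] - 1) + 1):
            found.add((bin_label(bp_from[chrom], b), bin_label(bp_to[chrom], b)))
        if end > n_bins[chrom] * bin_size:
            found.add((empty_state, empty_state))
        return found

    def counts_for_pair(key_from, key_to, n_bins):
        bp_from, bp_to = per_bp_states[key_from], per_bp_states[key_to]
        per_gene = {}
        for r in genes.table.itertuples():
            per_gene[r.gene_id] = gene_transitions(
                bp_from, bp_to, r.chrom, int(r.start), int(r.end), n_bins
            )
        rows = {}
        for sf in states:
            for st in states:
                t = (sf, st)
                a = sum(t in ts for ts in per_gene.values())
                rows[t] = {
                    "a": a,
                    **{
                        set_id: sum(t in per_gene[g] for g in members if g in per_gene)
                        for set_id, members in gene_sets.items()
                    },
                }
        return rows

    return counts_for_pair
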