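import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from chromtrans import (
    DifferentiationOrder,
    GeneAnnotation,
    Segmentation,
    binned_states,
    build_transition_table,
    count_transitions,
    enumerate_sample_pairs,
    gene_transition_indicator,
    occurrence_rate,
    transition_category_count,
)

from conftest import brute_force_counts, make_segmentation

STATES = ["Emp", "A", "B", "C"]


def order_of(rep_counts, names=None):
    names = names or [f"CT{i}" for i in range(len(rep_counts))]
    reps = {n: tuple(f"R{j}" for j in range(c)) for n, c in zip(names, rep_counts)}
    return DifferentiationOrder(tuple(names), reps)


class TestEnumerateSamplePairs:
    def test_between_type_pair_count(self):
        pairs = enumerate_sample_pairs(order_of([2, 3, 2], ["MSC", "PC", "HC"]))
        msc_pc = [p for p in pairs if (p.cell_from, p.cell_to) == ("MSC", "PC")]
        assert len(msc_pc) == 6

    def test_within_type_two_replicates_single_pair(self):
        pairs = enumerate_sample_pairs(order_of([2]))
        within = [p for p in pairs if p.within_type]
        assert len(within) == 1
        assert within[0].rep_from != within[0].rep_to

    def test_total_pair_count_formula(self):
        for rep_counts in [(2, 3, 2), (1, 1), (3,), (2, 2, 2, 2)]:
            pairs = enumerate_sample_pairs(order_of(list(rep_counts)))
            expected = sum(
                ru * rv for ru, rv in itertools.combinations(rep_counts, 2)
            ) + sum(comb(r, 2) for r in rep_counts)
            assert len(pairs) == expected

    def test_seed_reproducibility_and_direction_randomness(self):
        order = order_of([3, 2])
        assert enumerate_sample_pairs(order, 42) == enumerate_sample_pairs(order, 42)
        directions = {
            tuple(
                (p.rep_from, p.rep_to)
                for p in enumerate_sample_pairs(order, seed)
                if p.within_type
            )
            for seed in range(20)
        }
        assert len(directions) > 1  # direction actually depends on the seed


class TestTransitionCategoryCount:
    @pytest.mark.parametrize(
        "n_cell_types, n_states, expected",
        [(3, 15, 1350), (1, 1, 1), (4, 15, 2250), (2, 5, 75)],
    )
    def test_formula(self, n_cell_types, n_states, expected):
        assert transition_category_count(n_cell_types, n_states) == expected

    def test_matches_enumeration(self):
        # with >=2 replicates everywhere, every within- and between-type
        # cell pair is realized by at least one sample pair
        order = order_of([2, 3, 2])
        pairs = enumerate_sample_pairs(order)
        cell_pairs = {(p.cell_from, p.cell_to) for p in pairs}
        assert len(cell_pairs) * 15**2 == transition_category_count(3, 15)


class TestBinnedStates:
    def test_aligned_segments_read_off_directly(self):
        seg = make_segmentation({"chr1": ["A", "B", "A"]}, bin_size=200)
        bins = binned_states(seg, 200, STATES, "Emp")
        assert [STATES[c] for c in bins["chr1"]] == ["A", "B", "A"]

    def test_majority_rule_on_straddling_bin(self):
        seg = Segmentation(
            pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [150], "state": ["A"]}
            )
        )
        bins = binned_states(seg, 200, STATES, "Emp")
        assert STATES[bins["chr1"][0]] == "A"  # 150 bp A vs 50 bp empty

    def test_minority_segment_loses_to_empty(self):
        seg = Segmentation(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50], "state": ["A"]})
        )
        bins = binned_states(seg, 200, STATES, "Emp")
        assert STATES[bins["chr1"][0]] == "Emp"

    def test_tie_breaks_to_first_configured_state(self):
        seg = Segmentation(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [0, 100],
                    "end": [100, 200],
                    "state": ["B", "A"],
                }
            )
        )
        bins = binned_states(seg, 200, ["Emp", "A", "B"], "Emp")
        assert bins["chr1"][0] == 1  # "A" precedes "B" in the alphabet

    def test_uncovered_region_is_empty_state(self):
        seg = make_segmentation({"chr1": ["A"]}, bin_size=200)
        bins = binned_states(seg, 200, STATES, "Emp", chrom_bins={"chr1": 5})
        assert [STATES[c] for c in bins["chr1"]] == ["A", "Emp", "Emp", "Emp", "Emp"]


class TestGeneTransitionIndicator:
    def make_bins(self, labels):
        return {"chr1": np.array([STATES.index(s) for s in labels], dtype=np.int32)}

    def genes_one(self, start, end):
        return GeneAnnotation(
            pd.DataFrame(
                {"gene_id": ["g"], "chrom": ["chr1"], "start": [start], "end": [end], "strand": ["+"]}
            )
        )

    def decode(self, ind):
        n = len(STATES)
        return {
            (STATES[c // n], STATES[c % n]) for c in np.flatnonzero(ind[0])
        }

    def test_identical_samples_only_self_transitions(self):
        bins = self.make_bins(["A", "B", "A"])
        ind = gene_transition_indicator(bins, bins, self.genes_one(0, 600), 200, 4, 0)
        assert self.decode(ind) == {("A", "A"), ("B", "B")}

    def test_three_bin_enumeration(self):
        ind = gene_transition_indicator(
            self.make_bins(["A", "A", "B"]),
            self.make_bins(["A", "C", "B"]),
            self.genes_one(0, 600),
            200,
            4,
            0,
        )
        assert self.decode(ind) == {("A", "A"), ("A", "C"), ("B", "B")}

    def test_gene_outside_tiled_region_gets_empty_self_transition(self):
        ind = gene_transition_indicator(
            self.make_bins(["A"]), self.make_bins(["B"]),
            self.genes_one(1000, 1400), 200, 4, 0,
        )
        assert self.decode(ind) == {("Emp", "Emp")}

    def test_gene_on_missing_chrom_gets_empty_self_transition(self):
        genes = GeneAnnotation(
            pd.DataFrame(
                {"gene_id": ["g"], "chrom": ["chr9"], "start": [0], "end": [100], "strand": ["."]}
            )
        )
        ind = gene_transition_indicator(
            self.make_bins(["A"]), self.make_bins(["A"]), genes, 200, 4, 0
        )
        assert self.decode(ind) == {("Emp", "Emp")}


class TestCountTransitions:
    def build(self, rng, n_genes=20, n_bins=30):
        starts = np.sort(rng.choice(n_bins * 200 - 400, size=n_genes, replace=False))
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n_genes)],
                    "chrom": "chr1",
                    "start": starts,
                    "end": starts + rng.integers(200, 900, size=n_genes),
                    "strand": ".",
                }
            )
        )
        return genes

    def test_set_equal_background_gives_s_equal_a(self, toy_genes):
        bins = {"chr1": np.zeros(20, dtype=np.int32), "chr2": np.zeros(10, dtype=np.int32)}
        ind = gene_transition_indicator(bins, bins, toy_genes, 200, 4, 0)
        pairs = enumerate_sample_pairs(order_of([2]))
        tab = count_transitions(ind, toy_genes, {"all": toy_genes.gene_ids}, STATES, pairs[0])
        assert (tab["s"] == tab["a"]).all()
        assert (tab["S"] == tab["A"]).all()

    def test_zero_count_rows_kept(self, toy_genes):
        bins = {"chr1": np.zeros(20, dtype=np.int32), "chr2": np.zeros(10, dtype=np.int32)}
        ind = gene_transition_indicator(bins, bins, toy_genes, 200, 4, 0)
        pair = enumerate_sample_pairs(order_of([2]))[0]
        tab = count_transitions(ind, toy_genes, {"set": ["g1"]}, STATES, pair)
        assert len(tab) == len(STATES) ** 2
        assert (tab["s"] <= tab["a"]).all()  # set is a subset of the background

    def test_counts_match_brute_force_on_random_fixtures(self):
        """Vectorized counting equals a naive per-gene, per-bin double loop."""
        bin_size = 200
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_states = int(rng.integers(3, 6))
            states = ["Emp"] + [f"S{i}" for i in range(n_states - 1)]
            n_bins = 40
            genes = self.build(rng)
            gene_sets = {"setA": list(rng.choice(genes.gene_ids, size=7, replace=False))}
            # random, deliberately non-bin-aligned segmentations
            per_bp = {}
            segs = {}
            for key in ["X", "Y"]:
                breaks = np.sort(
                    rng.choice(np.arange(1, n_bins * bin_size), size=25, replace=False)
                )
                edges = np.concatenate([[0], breaks, [n_bins * bin_size]])
                labels = rng.choice(states, size=edges.size - 1)
                seg = Segmentation(
                    pd.DataFrame(
                        {
                            "chrom": "chr1",
                            "start": edges[:-1],
                            "end": edges[1:],
                            "state": labels,
                        }
                    )
                )
                segs[key] = seg
                bp = np.empty(n_bins * bin_size, dtype=object)
                for s, e, lab in zip(edges[:-1], edges[1:], labels):
                    bp[s:e] = lab
                per_bp[key] = {"chr1": bp}

            oracle = brute_force_counts(per_bp, genes, gene_sets, states, bin_size, "Emp")
            expected = oracle("X", "Y", {"chr1": n_bins})

            bins_x = binned_states(segs["X"], bin_size, states, "Emp", {"chr1": n_bins})
            bins_y = binned_states(segs["Y"], bin_size, states, "Emp", {"chr1": n_bins})
            ind = gene_transition_indicator(
                bins_x, bins_y, genes, bin_size, len(states), 0
            )
            pair = enumerate_sample_pairs(order_of([2]))[0]
            tab = count_transitions(ind, genes, gene_sets, states, pair)
            for r in tab.itertuples():
                exp = expected[(r.state_from, r.state_to)]
                assert r.a == exp["a"], (seed, r.state_from, r.state_to)
                assert r.s == exp["setA"]


class TestBuildTransitionTable:
    def segs(self, labels_by_sample, order):
        segs = []
        for (ct, rep), labels in labels_by_sample.items():
            segs.append(
                make_segmentation({"chr1": labels}, bin_size=200, cell_type=ct, replicate=rep)
            )
        return segs

    def test_identical_replicates_only_self_transitions(self, toy_genes):
        order = order_of([2], ["CT0"])
        labels = ["A", "B", "A", "Emp", "C"] * 4
        segs = self.segs({("CT0", "R0"): labels, ("CT0", "R1"): labels}, order)
        genes = toy_genes.subset(["g1", "g2", "g3"])
        tab = build_transition_table(
            segs, order, genes, {"set": ["g1"]}, 200, STATES, "Emp"
        )
        nonzero = tab[tab["a"] > 0]
        assert (nonzero["state_from"] == nonzero["state_to"]).all()

    def test_reversed_order_mirrors_between_type_counts(self, toy_genes):
        rng = np.random.default_rng(3)
        genes = toy_genes.subset(["g1", "g2", "g3"])
        fwd_order = order_of([2, 2], ["U", "V"])
        rev_order = DifferentiationOrder(("V", "U"), fwd_order.replicates)
        samples = {
            (ct, rep): list(rng.choice(STATES, size=20))
            for ct in ["U", "V"]
            for rep in ["R0", "R1"]
        }
        segs = self.segs(samples, fwd_order)
        fwd = build_transition_table(segs, fwd_order, genes, {"s": ["g1"]}, 200, STATES, "Emp")
        rev = build_transition_table(segs, rev_order, genes, {"s": ["g1"]}, 200, STATES, "Emp")
        f = fwd[(fwd.cell_from == "U") & (fwd.cell_to == "V")]
        r = rev[(rev.cell_from == "V") & (rev.cell_to == "U")]
        key_f = f.set_index(["rep_from", "rep_to", "state_from", "state_to"])["a"]
        key_r = r.set_index(["rep_to", "rep_from", "state_to", "state_from"])["a"]
        key_r.index.names = key_f.index.names
        assert key_f.sort_index().equals(key_r.sort_index())


class TestOccurrenceRate:
    def run_config(self, rep_counts, names, cell_pairs, always_gene="g1"):
        order = order_of(rep_counts, names)
        pairs = enumerate_sample_pairs(order)
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2"],
                    "chrom": "chr1",
                    "start": [0, 400],
                    "end": [200, 600],
                    "strand": ".",
                }
            )
        )
        n_states = len(STATES)
        transitions = [("A", "C"), ("B", "C")]
        t_codes = [
            STATES.index(x) * n_states + STATES.index(y) for x, y in transitions
        ]
        indicators = {}
        for p in pairs:
            ind = np.zeros((2, n_states**2), dtype=bool)
            ind[0, t_codes] = True  # g1 always shows both transitions
            indicators[p] = ind
        counts, maximum = occurrence_rate(
            indicators, genes, ["g1", "g2"], transitions, cell_pairs, STATES
        )
        return counts, maximum

    def test_maximum_two_by_three_replicates(self):
        counts, maximum = self.run_config([2, 3], ["MSC", "PC"], [("MSC", "PC")])
        assert maximum == 12
        assert counts["g1"] == 12
        assert counts["g2"] == 0

    def test_maximum_three_by_two_replicates(self):
        _, maximum = self.run_config([3, 2], ["PC", "HC"], [("PC", "HC")])
        assert maximum == 12

    def test_pooled_cell_pairs_maximum_from_first_principles(self):
        # (2, 3, 2) replicates pooled over MSC->PC and MSC->HC:
        # (2*3 + 2*2) replicate pairs x 2 transitions
        _, maximum = self.run_config(
            [2, 3, 2], ["MSC", "PC", "HC"], [("MSC", "PC"), ("MSC", "HC")]
        )
        assert maximum == 20
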