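"""Synthetic multi-cell-type, multi-replicate segmentations with known truth.

Two generators:

* :func:`simulate_segmentations` emits a complete input bundle (segmentation
  BEDs on a toy genome, a gene annotation, gene-set lists, a YAML config)
  in which designated gene sets undergo a planted, direction-dependent state
  transition between two cell types with a chosen probability, on top of a
  drifting background; replicate noise flips bin states independently.
* :func:`simulate_counts` draws count-table rows directly from the
  generative beta-binomial model, for testing the fitting stage in
  isolation with known proportions.

The default toy genome (one 2-Mbp chromosome, 500 genes of ~2 kbp, 200-bp
bins) keeps a full count-fit-effect-size run in the minutes range on one CPU
while preserving the multi-replicate, multi-cell-type structure of real
segmentation data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .counting import COUNT_COLUMNS, DifferentiationOrder
from .intervals import GeneAnnotation, Segmentation, write_bed

__all__ = [
    "PlantedSet",
    "SyntheticSpec",
    "simulate_segmentations",
    "simulate_counts",
    "simulate_count_grid",
    "write_bundle",
]

DEFAULT_STATES = ["Emp", "ActProm", "ActGene", "TxGene", "RepActPro"]


@dataclass(frozen=True)
class PlantedSet:
    """A gene set with an elevated transition probability.

    Genes of the set undergo the transition ``state_from -> state_to``
    between ``cell_from`` and ``cell_to`` with probability ``prob`` (per
    gene); non-planted genes follow the background dynamics.
    """

    gene_ids: tuple[str, ...]
    state_from: str
    state_to: str
    cell_from: str
    cell_to: str
    prob: float


@dataclass
class SyntheticSpec:
    """Parameters of the toy-genome segmentation simulator."""

    state_labels: Sequence[str] = field(default_factory=lambda: list(DEFAULT_STATES))
    empty_state: str = "Emp"
    cell_types: Sequence[str] = ("CTA", "CTB")
    replicates_per_type: Sequence[int] = (3, 3)
    n_genes: int = 500
    gene_length_mean: float = 2000.0
    gene_length_sd: float = 400.0
    genome_length: int = 2_000_000
    bin_size: int = 200
    change_prob: float = 0.05
    noise: float = 0.0
    planted_sets: Mapping[str, PlantedSet] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.empty_state not in self.state_labels:
            raise ValueError("empty_state must be in state_labels")
        if len(self.replicates_per_type) != len(self.cell_types):
            raise ValueError("replicates_per_type must match cell_types")
        for p in [self.change_prob, self.noise]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for ps in self.planted_sets.values():
            if not 0.0 <= ps.prob <= 1.0:
                raise ValueError("planted probability must lie in [0, 1]")
            for ct in (ps.cell_from, ps.cell_to):
                if ct not in self.cell_types:
                    raise ValueError(f"planted cell type {ct!r} not in cell_types")
            for st in (ps.state_from, ps.state_to):
                if st not in self.state_labels:
                    raise ValueError(f"planted state {st!r} not in state_labels")

    def order(self) -> DifferentiationOrder:
        reps = {
            ct: tuple(f"R{i + 1}" for i in range(n))
            for ct, n in zip(self.cell_types, self.replicates_per_type)
        }
        return DifferentiationOrder(tuple(self.cell_types), reps)


def _make_genes(spec: SyntheticSpec, rng: np.random.Generator) -> GeneAnnotation:
    """Place non-overlapping genes along the toy chromosome."""
    total_gene_bp = spec.n_genes * spec.gene_length_mean
    if total_gene_bp >= spec.genome_length:
        raise ValueError("genes do not fit the genome; reduce n_genes or lengths")
    avg_gap = (spec.genome_length - total_gene_bp) / (spec.n_genes + 1)
    rows = []
    cur = 0
    for i in range(spec.n_genes):
        gap = int(rng.uniform(0.2, 1.8) * avg_gap)
        length = max(int(rng.normal(spec.gene_length_mean, spec.gene_length_sd)), spec.bin_size)
        start = cur + gap
        end = start + length
        if end > spec.genome_length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene{i:04d}", "chr1", start, end, strand))
        cur = end
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(df)


def _segmentation_from_bins(
    bins: np.ndarray, spec: SyntheticSpec, cell_type: str, replicate: str
) -> Segmentation:
    """Collapse a per-bin label array into run-length BED segments."""
    change = np.flatnonzero(bins[1:] != bins[:-1]) + 1
    starts = np.concatenate([[0], change]) * spec.bin_size
    ends = np.concatenate([change, [bins.size]]) * spec.bin_size
    labels = [spec.state_labels[c] for c in bins[np.concatenate([[0], change])]]
    df = pd.DataFrame({"chrom": "chr1", "start": starts, "end": ends, "state": labels})
    return Segmentation(
        df, sample_id=f"{cell_type}_{replicate}", cell_type=cell_type, replicate=replicate
    )


def simulate_segmentations(
    spec: SyntheticSpec,
) -> tuple[list[Segmentation], GeneAnnotation, pd.DataFrame]:
    """Generate per-replicate segmentations, the annotation, and the truth.

    The first cell type's consensus assigns each bin an i.i.d. state (the
    empty state is given weight equal to all other states combined, making
    undecorated chromatin the most common label); each later cell type
    redraws every bin with probability ``change_prob``. Planted gene sets
    then overwrite the gene-body bins of the designated cell pair. Replicates
    flip each bin to a random other state with probability ``noise``. The
    truth table lists every (gene, transition, cell pair) actually planted.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _make_genes(spec, rng)
    n_states = len(spec.state_labels)
    n_bins = -(-spec.genome_length // spec.bin_size)
    empty_code = spec.state_labels.index(spec.empty_state)

    weights = np.ones(n_states)
    weights[empty_code] = n_states - 1
    weights /= weights.sum()

    consensus: dict[str, np.ndarray] = {}
    prev = None
    for ct in spec.cell_types:
        if prev is None:
            bins = rng.choice(n_states, size=n_bins, p=weights)
        else:
            bins = prev.copy()
            redraw = rng.random(n_bins) < spec.change_prob
            bins[redraw] = rng.choice(n_states, size=int(redraw.sum()), p=weights)
        consensus[ct] = bins
        prev = bins

    gene_bins = {}
    for r in genes.table.itertuples():
        b0 = int(r.start) // spec.bin_size
        b1 = (int(r.end) - 1) // spec.bin_size
        gene_bins[r.gene_id] = (b0, b1 + 1)

    truth_rows = []
    for set_id, ps in spec.planted_sets.items():
        c_from = spec.state_labels.index(ps.state_from)
        c_to = spec.state_labels.index(ps.state_to)
        for gid in ps.gene_ids:
            if gid not in gene_bins:
                raise ValueError(f"planted gene {gid!r} not in annotation")
            if rng.random() < ps.prob:
                b0, b1 = gene_bins[gid]
                consensus[ps.cell_from][b0:b1] = c_from
                consensus[ps.cell_to][b0:b1] = c_to
                truth_rows.append(
                    {
                        "gene_set": set_id,
                        "gene_id": gid,
                        "state_from": ps.state_from,
                        "state_to": ps.state_to,
                        "cell_from": ps.cell_from,
                        "cell_to": ps.cell_to,
                    }
                )

    segmentations = []
    order = spec.order()
    for ct in spec.cell_types:
        for rep in order.replicates[ct]:
            bins = consensus[ct].copy()
            if spec.noise > 0:
                flip = rng.random(n_bins) < spec.noise
                shift = rng.integers(1, n_states, size=int(flip.sum()))
                bins[flip] = (bins[flip] + shift) % n_states
            segmentations.append(_segmentation_from_bins(bins, spec, ct, rep))

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_set", "gene_id", "state_from", "state_to", "cell_from", "cell_to"],
    )
    return segmentations, genes, truth


def write_bundle(spec: SyntheticSpec, out_dir) -> Path:
    """Write a self-contained input bundle (BEDs, gene sets, YAML config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    segmentations, genes, truth = simulate_segmentations(spec)
    samples = []
    for seg in segmentations:
        path = out / f"{seg.sample_id}_segments.bed"
        write_bed(seg, path)
        samples.append(
            {"path": path.name, "cell_type": seg.cell_type, "replicate": seg.replicate}
        )
    write_bed(genes, out / "genes.bed")
    sets_manifest = []
    for set_id, ps in spec.planted_sets.items():
        set_path = out / f"genes_{set_id}.txt"
        set_path.write_text("\n".join(ps.gene_ids) + "\n")
        sets_manifest.append({"gene_set": set_id, "path": set_path.name})
    pd.DataFrame(sets_manifest, columns=["gene_set", "path"]).to_csv(
        out / "gene_sets.csv", index=False
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    config = {
        "samples": samples,
        "order": list(spec.cell_types),
        "bin_size": spec.bin_size,
        "state_labels": list(spec.state_labels),
        "empty_state": spec.empty_state,
        "annotation": "genes.bed",
        "gene_sets": "gene_sets.csv",
        "seed": spec.seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return out / "config.yaml"


def _betabin_draws(
    rng: np.random.Generator, n: int, p: float, precision: float, size: int
) -> np.ndarray:
    """Draw beta-binomial counts via the Beta-then-Binomial construction."""
    if p <= 0.0:
        return np.zeros(size, dtype=int)
    if p >= 1.0:
        return np.full(size, n, dtype=int)
    probs = rng.beta(p * precision, (1.0 - p) * precision, size=size)
    return rng.binomial(n, probs)


def simulate_counts(
    S: int,
    A: int,
    p_set: float,
    p_bg: float,
    precision: float = 50.0,
    n_replicate_pairs: int = 6,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Count-table rows for one (t, d) cell from the generative model.

    Shapes are ``alpha = p * precision`` and ``beta = (1 - p) * precision``;
    large precision approaches the plain binomial. Returns one row per
    replicate pair with columns (s, S, a, A) plus placeholder labels.
    """
    for p in (p_set, p_bg):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if precision <= 0:
        raise ValueError("precision must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = _betabin_draws(rng, S, p_set, precision, n_replicate_pairs)
    a = _betabin_draws(rng, A, p_bg, precision, n_replicate_pairs)
    return pd.DataFrame(
        {
            "gene_set": "set",
            "cell_from": "CTA",
            "cell_to": "CTB",
            "rep_from": [f"i{j}" for j in range(n_replicate_pairs)],
            "rep_to": [f"j{j}" for j in range(n_replicate_pairs)],
            "state_from": "S0",
            "state_to": "S1",
            "s": s,
            "S": S,
            "a": a,
            "A": A,
        }
    )[COUNT_COLUMNS]


def simulate_count_grid(
    n_states: int = 5,
    cell_types: Sequence[str] = ("CTA", "CTB"),
    S: int = 100,
    A: int = 20000,
    p_set: float = 0.05,
    p_bg: float = 0.05,
    precision: float = 50.0,
    n_replicate_pairs: int = 6,
    planted: Mapping[tuple[str, str, str, str], float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """A full (state pair x cell pair) grid of simulated count rows.

    Every cell is drawn with (p_set, p_bg) except cells listed in
    ``planted``, keyed by (state_from, state_to, cell_from, cell_to), whose
    set probability is replaced by the planted value.
    """
    rng = np.random.default_rng(seed)
    states = [f"S{i}" for i in range(n_states)]
    cell_pairs = [
        (u, v) for i, u in enumerate(cell_types) for v in cell_types[i:]
    ]
    frames = []
    planted = planted or {}
    for sf, st in itertools.product(states, states):
        for cf, ct in cell_pairs:
            p = planted.get((sf, st, cf, ct), p_set)
            rows = simulate_counts(S, A, p, p_bg, precision, n_replicate_pairs, rng)
            rows["state_from"] = sf
            rows["state_to"] = st
            rows["cell_from"] = cf
            rows["cell_to"] = ct
            frames.append(rows)
    return pd.concat(frames, ignore_index=True)
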