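"""Genomic interval containers and exact base-pair interval algebra.

All coordinates are 0-based half-open (BED convention). Interval sets are
kept normalized: per chromosome, sorted, with overlapping *and touching*
intervals merged, so every set has a unique canonical representation and
base-pair arithmetic (intersection, union, Jaccard) is exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneAnnotation",
    "Segmentation",
    "BedParseError",
    "read_bed",
    "write_bed",
    "jaccard",
    "overlap_bp",
]


class BedParseError(ValueError):
    """Raised when a BED-like file contains a malformed or invalid line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _normalize_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping/touching [start, end) pairs on one chromosome."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # a new run begins wherever the start exceeds the running max of prior ends
    run_end = np.maximum.accumulate(ends)
    new_run = np.empty(starts.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > run_end[:-1]
    idx = np.flatnonzero(new_run)
    merged_starts = starts[idx]
    merged_ends = np.empty(idx.size, dtype=ends.dtype)
    merged_ends[:-1] = run_end[idx[1:] - 1]
    merged_ends[-1] = run_end[-1]
    return merged_starts, merged_ends


class IntervalSet:
    """A normalized collection of genomic intervals.

    Stored per chromosome as sorted, non-overlapping numpy arrays of starts
    and ends; touching intervals are merged at construction so equality of
    region content implies equality of representation.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._data[chrom] = _normalize_arrays(arr[:, 0], arr[:, 1])

    @classmethod
    def from_arrays(cls, data: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> "IntervalSet":
        obj = cls()
        for chrom, (starts, ends) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if starts.size:
                if np.any(starts < 0) or np.any(starts >= ends):
                    raise ValueError(f"invalid intervals on {chrom}")
                obj._data[chrom] = _normalize_arrays(starts, ends)
        return obj

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._data.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            starts, ends = self._data[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield GenomicInterval(chrom, s, e)

    def __len__(self) -> int:
        return sum(starts.size for starts, _ in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c][0], other._data[c][0])
            and np.array_equal(self._data[c][1], other._data[c][1])
            for c in self._data
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_bp()} bp)"

    def total_bp(self) -> int:
        return int(sum((ends - starts).sum() for starts, ends in self._data.values()))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-pair-wise intersection with another set."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in set(self._data) & set(other._data):
            a_s, a_e = self._data[chrom]
            b_s, b_e = other._data[chrom]
            starts, ends = _intersect_arrays(a_s, a_e, b_s, b_e)
            if starts.size:
                out[chrom] = (starts, ends)
        res = IntervalSet()
        res._data = out
        return res

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in set(self._data) | set(other._data):
            a_s, a_e = self.arrays(chrom)
            b_s, b_e = other.arrays(chrom)
            starts = np.concatenate([a_s, b_s])
            ends = np.concatenate([a_e, b_e])
            out[chrom] = _normalize_arrays(starts, ends)
        res = IntervalSet()
        res._data = out
        return res

    def filter_chroms(self, allowed: Sequence[str]) -> "IntervalSet":
        """Restrict to an allow-list of chromosome names."""
        res = IntervalSet()
        res._data = {c: v for c, v in self._data.items() if c in set(allowed)}
        return res

    def to_frame(self) -> pd.DataFrame:
        rows = [(iv.chrom, iv.start, iv.end) for iv in self]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _intersect_arrays(
    a_s: np.ndarray, a_e: np.ndarray, b_s: np.ndarray, b_e: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pointer intersection of normalized interval arrays."""
    out_s: list[int] = []
    out_e: list[int] = []
    i = j = 0
    while i < a_s.size and j < b_s.size:
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if lo < hi:
            out_s.append(int(lo))
            out_e.append(int(hi))
        if a_e[i] <= b_e[j]:
            i += 1
        else:
            j += 1
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def overlap_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Exact intersection length in base pairs (symmetric)."""
    return a.intersect(b).total_bp()


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair Jaccard index: intersection bp / union bp.

    Returns 0.0 when the union is empty.
    """
    inter = overlap_bp(a, b)
    union = a.total_bp() + b.total_bp() - inter
    if union == 0:
        return 0.0
    return inter / union


@dataclass
class GeneAnnotation:
    """Gene bodies keyed by a unique gene identifier.

    Backed by a DataFrame with columns (gene_id, chrom, start, end, strand).
    Strand is carried through but ignored by interval arithmetic.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id in annotation: {dup!r}")
        bad = self.table[(self.table["start"] < 0) | (self.table["start"] >= self.table["end"])]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(f"invalid gene interval {r.gene_id}: {r.start}-{r.end}")
        self.table = self.table.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def lengths(self) -> pd.Series:
        return (self.table["end"] - self.table["start"]).set_axis(self.table["gene_id"])

    def subset(self, gene_ids: Sequence[str]) -> "GeneAnnotation":
        wanted = set(gene_ids)
        sub = self.table[self.table["gene_id"].isin(wanted)]
        return GeneAnnotation(sub.copy())

    def resolve(self, gene_ids: Sequence[str]) -> tuple[list[str], list[str]]:
        """Split ids into (resolvable, unresolvable) against this annotation."""
        known = set(self.table["gene_id"])
        found = [g for g in gene_ids if g in known]
        missing = [g for g in gene_ids if g not in known]
        return found, missing

    def body_intervals(self, gene_ids: Sequence[str] | None = None) -> IntervalSet:
        """Union of gene bodies (overlapping genes are not double-counted)."""
        tab = self.table if gene_ids is None else self.subset(gene_ids).table
        return IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in tab.itertuples()
        )


@dataclass
class Segmentation:
    """One sample's tiling of the genome into labeled chromatin states.

    ``segments`` holds columns (chrom, start, end, state); per chromosome the
    segments are sorted and non-overlapping.
    """

    segments: pd.DataFrame
    sample_id: str = ""
    cell_type: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        req = ["chrom", "start", "end", "state"]
        missing = [c for c in req if c not in self.segments.columns]
        if missing:
            raise ValueError(f"segmentation missing columns: {missing}")
        seg = self.segments.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in seg.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts < 0) or np.any(starts >= ends):
                raise ValueError(f"invalid segment coordinates on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
        self.segments = seg

    @property
    def states(self) -> list[str]:
        return sorted(self.segments["state"].unique())

    def chrom_extent(self) -> dict[str, int]:
        """Highest covered coordinate per chromosome."""
        return self.segments.groupby("chrom")["end"].max().astype(int).to_dict()

    def state_regions(self, state: str) -> IntervalSet:
        sub = self.segments[self.segments["state"] == state]
        return IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in sub.itertuples()
        )

    def validate_states(self, alphabet: Sequence[str]) -> None:
        unknown = set(self.segments["state"]) - set(alphabet)
        if unknown:
            raise ValueError(f"states outside configured alphabet: {sorted(unknown)}")


def _parse_lines(path_or_buf) -> Iterator[tuple[int, list[str]]]:
    if hasattr(path_or_buf, "read"):
        handle = path_or_buf
        close = False
    else:
        handle = open(path_or_buf)
        close = True
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track") or line.startswith("browser"):
                continue
            yield lineno, line.split("\t")
    finally:
        if close:
            handle.close()


def _coords(fields: list[str], lineno: int, n_min: int) -> tuple[str, int, int]:
    if len(fields) < n_min:
        raise BedParseError(f"line {lineno}: expected >= {n_min} tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    if not (0 <= start < end):
        raise BedParseError(f"line {lineno}: invalid coordinates {start} >= {end}")
    return chrom, start, end


def read_bed(path, dialect: str = "peak", **meta):
    """Read a BED-like file.

    Parameters
    ----------
    path : path or file-like
        Tab-separated input; ``#``/``track``/``browser`` lines are skipped.
    dialect : {"peak", "segmentation", "annotation"}
        * ``peak``: BED3+, returns a normalized :class:`IntervalSet`.
        * ``segmentation``: BED4 with a state label in column 4, returns a
          :class:`Segmentation` (metadata may be passed as keyword arguments).
        * ``annotation``: BED6-like with gene_id in column 4 and strand in
          column 6 (``.`` if absent), returns a :class:`GeneAnnotation`.
    """
    if dialect == "peak":
        ivs = []
        for lineno, fields in _parse_lines(path):
            chrom, start, end = _coords(fields, lineno, 3)
            ivs.append(GenomicInterval(chrom, start, end))
        return IntervalSet(ivs)
    if dialect == "segmentation":
        rows = []
        for lineno, fields in _parse_lines(path):
            chrom, start, end = _coords(fields, lineno, 4)
            rows.append((chrom, start, end, fields[3]))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        return Segmentation(df, **meta)
    if dialect == "annotation":
        rows = []
        for lineno, fields in _parse_lines(path):
            chrom, start, end = _coords(fields, lineno, 4)
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in {"+", "-", "."}:
                raise BedParseError(f"line {lineno}: invalid strand {strand!r}")
            rows.append((fields[3], chrom, start, end, strand))
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        return GeneAnnotation(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_bed(obj, path) -> None:
    """Write an IntervalSet, Segmentation or GeneAnnotation as BED text."""
    if hasattr(path, "write"):
        handle, close = path, False
    else:
        handle, close = open(path, "w"), True
    try:
        if isinstance(obj, IntervalSet):
            for iv in obj:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        elif isinstance(obj, Segmentation):
            for r in obj.segments.itertuples():
                handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\n")
        elif isinstance(obj, GeneAnnotation):
            for r in obj.table.itertuples():
                handle.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")
        else:
            raise TypeError(f"cannot write {type(obj).__name__}")
    finally:
        if close:
            handle.close()
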