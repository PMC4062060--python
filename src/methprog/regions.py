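"""Genomic interval primitives: containers, BED I/O, overlap counting and shuffling.

Coordinates are 0-based half-open throughout, matching BED semantics, so
interval files round-trip without arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "overlap_indicator",
    "overlap_count",
    "permute_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into a list of intervals (name/strand kept when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else None
        strand = str(row[5]) if len(row) > 5 else None
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), name, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (name defaults to '.', score fixed at 0, strand to '.')."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand or '.'}\n"
            )


def _by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    chroms: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        chroms.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in chroms.items():
        arr = np.array(sorted(pairs), dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns ``{chrom: (starts, ends)}`` with disjoint, sorted intervals, so both
    arrays are strictly increasing — the property the sweep below relies on.
    """
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends) in _by_chrom(intervals).items():
        m_starts: list[int] = []
        m_ends: list[int] = []
        for s, e in zip(starts, ends):
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        merged[chrom] = (
            np.array(m_starts, dtype=np.int64),
            np.array(m_ends, dtype=np.int64),
        )
    return merged


def _check_bounds(
    intervals: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> None:
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {chrom_sizes[iv.chrom]}"
            )


def overlap_indicator(
    query: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Boolean vector: does each query interval share >= 1 bp with any target?

    Sorted-merge + binary search: after merging, target ends are increasing, so
    the only candidate for query [s, e) is the last merged target starting
    before e; the query overlaps iff that target ends after s.
    """
    if chrom_sizes is not None:
        _check_bounds(query, chrom_sizes)
        _check_bounds(targets, chrom_sizes)
    merged = merge_intervals(targets)
    hit = np.zeros(len(query), dtype=bool)
    per_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(query):
        per_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in per_chrom.items():
        if chrom not in merged:
            continue
        t_starts, t_ends = merged[chrom]
        if len(t_starts) == 0:
            continue
        qs = np.array([query[i].start for i in idxs], dtype=np.int64)
        qe = np.array([query[i].end for i in idxs], dtype=np.int64)
        pos = np.searchsorted(t_starts, qe, side="left")
        ok = pos > 0
        ok[ok] &= t_ends[pos[ok] - 1] > qs[ok]
        hit[np.array(idxs)[ok]] = True
    return hit


def overlap_count(
    query: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int] | None = None,
) -> int:
    """Number of query intervals overlapping at least one target (each once)."""
    return int(overlap_indicator(query, targets, chrom_sizes).sum())


def permute_intervals(
    intervals: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    seed: int | np.random.Generator,
    within: Sequence[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Uniformly reposition each interval on its own chromosome, keeping length.

    The start of each interval is redrawn uniformly from the legal range
    [0, L_chrom - length]; chromosome assignment and interval lengths are
    preserved, which is the null model for the overlap permutation test.

    With ``within`` (e.g. the CpG-island universe), placements are restricted
    to that interval space instead: a containing interval on the same
    chromosome is chosen with probability proportional to its number of legal
    start positions, and the start is uniform inside it.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    _check_bounds(intervals, chrom_sizes)
    space = None
    if within is not None:
        space = {
            chrom: (starts, ends)
            for chrom, (starts, ends) in merge_intervals(within).items()
        }
    out = []
    for iv in intervals:
        if space is None:
            limit = chrom_sizes[iv.chrom] - iv.length
            if limit < 0:
                raise ValueError(
                    f"interval {iv.name or iv.chrom} longer than its chromosome"
                )
            s = int(rng.integers(0, limit + 1))
        else:
            starts, ends = space.get(iv.chrom, (np.array([]), np.array([])))
            slots = ends - starts - iv.length + 1
            slots = np.maximum(slots, 0)
            total = int(slots.sum())
            if total <= 0:
                raise ValueError(
                    f"no interval in the restricted space fits {iv.name or iv.chrom}"
                )
            j = int(rng.choice(len(starts), p=slots / total))
            s = int(rng.integers(starts[j], ends[j] - iv.length + 1))
        out.append(GenomicInterval(iv.chrom, s, s + iv.length, iv.name, iv.strand))
    return out
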