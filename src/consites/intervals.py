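"""Genomic coordinate primitives and BED-dialect I/O.

All coordinates are 0-based half-open (BED convention): ``start`` is the
first base of the interval, ``end`` is one past the last.  Every other
module builds on the types and predicates here.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "IntervalIndex",
    "read_bed",
    "write_bed",
    "normalize_peak",
    "overlaps",
    "center_within",
    "midpoint",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    # extra BED columns (name, score, ...) carried opaquely
    annotations: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor midpoint; for even lengths this is start + length/2
        return self.start + self.length // 2

    def identity(self) -> tuple:
        """Hashable (chrom, start, end, strand) key used for site identity."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak with its provenance.

    ``summit_offset`` (bp from start) is carried when a peak caller reports
    it but is unused by default: centering follows the peak midpoint.
    """

    interval: GenomicInterval
    source_cell_line: str = ""
    source_dataset: str = ""
    summit_offset: int | None = None


def midpoint(iv: GenomicInterval) -> int:
    return iv.midpoint


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def center_within(a: GenomicInterval, b: GenomicInterval, margin: int) -> bool:
    """True iff the interval midpoints are within ``margin`` bp (same chrom)."""
    return a.chrom == b.chrom and abs(a.midpoint - b.midpoint) <= margin


def normalize_peak(p: Peak, target_length: int = 200) -> Peak:
    """Extend/trim a peak to ``target_length`` bp centered on its midpoint.

    Clipped at position 0 if the centered window would run off the
    chromosome start (the result may then be shorter than the target).
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    iv = p.interval
    mid = iv.midpoint
    half = target_length // 2
    start = max(0, mid - half)
    end = start + target_length if mid - half >= 0 else mid + (target_length - half)
    if mid - half < 0:
        end = mid + (target_length - half)
    new_iv = GenomicInterval(iv.chrom, start, end, iv.strand, iv.annotations)
    return replace(p, interval=new_iv)


def read_bed(path, dialect: str = "bed6") -> list[GenomicInterval]:
    """Read a BED3/BED6/BED+ file into intervals, in file order.

    Columns beyond the dialect's strand column are preserved as opaque
    string annotations.  Malformed lines raise ``ValueError`` naming the
    line number.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = "."
            extra: Sequence[str] = fields[3:]
            if dialect != "bed3" and len(fields) >= 6:
                strand = fields[5] if fields[5] in VALID_STRANDS else "."
                extra = tuple(fields[3:5]) + tuple(fields[6:])
            try:
                out.append(GenomicInterval(chrom, start, end, strand, tuple(extra)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, dialect: str = "bed6") -> None:
    """Write intervals as tab-separated BED; round-trips read_bed exactly."""
    with open(path, "w") as fh:
        for iv in intervals:
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.annotations[0] if len(iv.annotations) >= 1 else "."
                score = iv.annotations[1] if len(iv.annotations) >= 2 else "0"
                rest = iv.annotations[2:]
                cols = [iv.chrom, str(iv.start), str(iv.end), str(name), str(score), iv.strand]
                cols.extend(str(x) for x in rest)
                fh.write("\t".join(cols) + "\n")


class IntervalIndex:
    """Overlap/stab queries over a fixed interval set via sorted arrays.

    Intervals are merged per chromosome at construction, so queries answer
    "does x overlap ANY input interval", which is what peak/region overlap
    tests need.  O(log n) per query.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for iv in intervals:
            by_chrom[iv.chrom].append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if starts is None or len(starts) == 0:
            return False
        ends = self._ends[iv.chrom]
        # candidate: last merged interval with start < iv.end
        i = int(np.searchsorted(starts, iv.end, side="left")) - 1
        return i >= 0 and ends[i] > iv.start

    def covers_point(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and self._ends[chrom][i] > pos


class PointIndex:
    """Nearest-point queries over a set of (chrom, position) points."""

    def __init__(self, points: Iterable[tuple[str, int]]):
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for chrom, pos in points:
            by_chrom[chrom].append(pos)
        self._pos = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}

    def any_within(self, chrom: str, pos: int, margin: int) -> bool:
        arr = self._pos.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = int(np.searchsorted(arr, pos))
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(int(arr[j]) - pos) <= margin:
                return True
        return False
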