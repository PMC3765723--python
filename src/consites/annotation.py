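"""Genomic context of site classes: TSS proximity, feature density, co-factor overlap.

Sites are categorized by a first-match-wins rule: within ±5 kb of any
TSS → "TSS"; else inside any gene body → "in_gene"; else "others".
Feature-density profiles report, at each offset around the site center,
the fraction of sites whose (center + offset) base is covered by a
feature (e.g. a CpG island).  Co-factor overlap asks how often another
protein's peak center falls within ±200 bp of a site center.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak, PointIndex

__all__ = [
    "GeneModel",
    "DensityProfile",
    "annotate_site",
    "annotate_sites",
    "feature_density_profile",
    "factor_overlap_fraction",
]

CATEGORIES = ("TSS", "in_gene", "others")


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS and its genomic span."""

    gene_id: str
    span: GenomicInterval  # TSS to transcription end, strand-aware

    @property
    def tss(self) -> int:
        return self.span.start if self.span.strand != "-" else self.span.end - 1

    @classmethod
    def from_bed(cls, iv: GenomicInterval, gene_id: str | None = None) -> "GeneModel":
        name = gene_id or (iv.annotations[0] if iv.annotations else "gene")
        return cls(name, iv)


@dataclass
class DensityProfile:
    """Per-offset coverage fraction around site centers."""

    offsets: np.ndarray  # -W..+W
    values: np.ndarray  # fractions in [0, 1]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for o, v in zip(self.offsets, self.values):
                fh.write(f"{o}\t{v:.6f}\n")


class _GeneIndex:
    def __init__(self, genes: Sequence[GeneModel]):
        self._tss = defaultdict(list)
        self._spans = defaultdict(list)
        for g in genes:
            self._tss[g.span.chrom].append(g.tss)
            self._spans[g.span.chrom].append((g.span.start, g.span.end))
        self._tss = {c: np.sort(np.array(v)) for c, v in self._tss.items()}
        for c in self._spans:
            self._spans[c].sort()

    def near_tss(self, chrom: str, pos: int, window: int) -> bool:
        arr = self._tss.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = int(np.searchsorted(arr, pos))
        return any(
            0 <= j < len(arr) and abs(int(arr[j]) - pos) <= window for j in (i - 1, i)
        )

    def in_gene(self, chrom: str, pos: int) -> bool:
        spans = self._spans.get(chrom, ())
        # spans are few in practice; linear scan over candidates via bisect
        for s, e in spans:
            if s > pos:
                break
            if s <= pos < e:
                return True
        return False


def annotate_site(
    site: GenomicInterval,
    genes: Sequence[GeneModel],
    tss_window: int = 5000,
    _index: _GeneIndex | None = None,
) -> str:
    """Categorize one site by its midpoint: TSS > in_gene > others."""
    idx = _index or _GeneIndex(genes)
    mid = site.midpoint
    if idx.near_tss(site.chrom, mid, tss_window):
        return "TSS"
    if idx.in_gene(site.chrom, mid):
        return "in_gene"
    return "others"


def annotate_sites(
    sites: Iterable[GenomicInterval], genes: Sequence[GeneModel], tss_window: int = 5000
) -> dict[str, int]:
    """Category counts for a site class (the pie-chart numbers)."""
    idx = _GeneIndex(genes)
    counts = {c: 0 for c in CATEGORIES}
    for s in sites:
        counts[annotate_site(s, genes, tss_window, _index=idx)] += 1
    return counts


def feature_density_profile(
    sites: Sequence[GenomicInterval],
    feature_intervals: Sequence[GenomicInterval],
    halfwidth: int = 2500,
) -> DensityProfile:
    """Fraction of sites covered by a feature at each offset in ±halfwidth.

    value[o] = (# sites with center + o inside >= 1 feature) / (# sites).
    """
    if not sites:
        raise ValueError("site list is empty")
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in feature_intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out: list[list[int]] = []
        for s, e in pairs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (
            np.array([p[0] for p in out]),
            np.array([p[1] for p in out]),
        )

    width = 2 * halfwidth + 1
    cover = np.zeros(width + 1)  # +1 slot for the diff trick
    for site in sites:
        got = merged.get(site.chrom)
        if got is None:
            continue
        starts, ends = got
        c = site.midpoint
        lo, hi = c - halfwidth, c + halfwidth + 1
        i = int(np.searchsorted(ends, lo, side="right"))
        while i < len(starts) and starts[i] < hi:
            a = max(int(starts[i]), lo) - lo
            b = min(int(ends[i]), hi) - lo
            cover[a] += 1
            cover[b] -= 1
            i += 1
    values = np.cumsum(cover)[:width] / len(sites)
    return DensityProfile(np.arange(-halfwidth, halfwidth + 1), values)


def factor_overlap_fraction(
    site_class: Sequence[GenomicInterval],
    factor_peaks: Sequence[Peak | GenomicInterval],
    margin: int = 200,
) -> float | None:
    """Fraction of sites with a factor-peak center within ±margin bp.

    Returns None (missing) for an empty site class.  Callers evaluating
    many cell lines run this once per (factor, cell line).
    """
    if not site_class:
        return None
    centers = []
    for p in factor_peaks:
        iv = p.interval if hasattr(p, "interval") else p
        centers.append((iv.chrom, iv.midpoint))
    idx = PointIndex(centers)
    hits = sum(1 for s in site_class if idx.any_within(s.chrom, s.midpoint, margin))
    return hits / len(site_class)
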