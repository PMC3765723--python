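"""ChIA-PET interaction overlap, enrichment, and fractional pair-type counting.

A ChIA-PET interaction is an unordered pair of genomic regions (region1,
region2) brought into proximity by the ChIP-ed protein; regions of
different pairs may overlap.  Three analyses live here:

* how many sites of a class fall inside any interaction region (a site
  counts once regardless of how many regions contain it);
* enrichment of one site class over another among interaction regions —
  sample odds ratio plus a one-sided Fisher exact p-value;
* fractional interaction typing: each pair carries unit weight spread
  uniformly over the label combinations of its two regions, so the type
  counts sum exactly to the number of pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex

__all__ = [
    "InteractionPair",
    "ContingencyTable2x2",
    "PairTypeCounts",
    "read_pairs",
    "write_pairs",
    "sites_in_interactions",
    "enrichment_test",
    "fractional_type_counts",
]

LABELS = ("cCTCF", "nonconst", "neither")
PAIR_TYPES = tuple(
    (LABELS[i], LABELS[j]) for i in range(3) for j in range(i, 3)
)


@dataclass(frozen=True)
class InteractionPair:
    region1: GenomicInterval
    region2: GenomicInterval
    pair_id: str = ""

    def swapped(self) -> "InteractionPair":
        return InteractionPair(self.region2, self.region1, self.pair_id)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (in-interaction, not) for two site classes: rows 1 and 2."""

    a: int  # class 1 in interaction
    b: int  # class 1 not
    c: int  # class 2 in interaction
    d: int  # class 2 not

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @classmethod
    def from_totals(cls, total1, in1, total2, in2) -> "ContingencyTable2x2":
        """Build from the (total sites, sites in interaction) presentation."""
        return cls(in1, total1 - in1, in2, total2 - in2)


@dataclass
class PairTypeCounts:
    """Possibly fractional counts over the six unordered pair types."""

    counts: dict[tuple[str, str], float]
    n_pairs: int

    def proportions(self) -> dict[tuple[str, str], float]:
        return {k: v / self.n_pairs for k, v in self.counts.items()}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("type1\ttype2\tcount\tpercent\n")
            for (t1, t2), v in self.counts.items():
                fh.write(f"{t1}\t{t2}\t{v:.2f}\t{100 * v / self.n_pairs:.1f}\n")


def read_pairs(path) -> list[InteractionPair]:
    """Read paired-BED: chrom1 start1 end1 chrom2 start2 end2 [id ...]."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"{path}:{lineno}: fewer than 6 fields")
        try:
            r1 = GenomicInterval(f[0], int(f[1]), int(f[2]))
            r2 = GenomicInterval(f[3], int(f[4]), int(f[5]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        out.append(InteractionPair(r1, r2, f[6] if len(f) > 6 else f"pair{lineno}"))
    return out


def write_pairs(pairs: Iterable[InteractionPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.region1.chrom}\t{p.region1.start}\t{p.region1.end}\t"
                f"{p.region2.chrom}\t{p.region2.start}\t{p.region2.end}\t{p.pair_id}\n"
            )


def sites_in_interactions(
    sites: Sequence[GenomicInterval], pairs: Sequence[InteractionPair]
) -> tuple[int, int]:
    """(sites overlapping any interaction region, total sites)."""
    regions = [r for p in pairs for r in (p.region1, p.region2)]
    idx = IntervalIndex(regions)
    inside = sum(1 for s in sites if idx.overlaps_any(s))
    return inside, len(sites)


def enrichment_test(
    table: ContingencyTable2x2, alternative: str = "greater"
) -> tuple[float, float]:
    """Sample odds ratio and one-sided Fisher exact p-value.

    The odds ratio is the cross-product (a/b)/(c/d); a zero denominator
    yields inf with a warning.  The p-value is the exact hypergeometric
    tail for class 1 being over-represented among in-interaction sites.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b == 0 or c == 0:
        warnings.warn("zero cell in the odds-ratio denominator; odds ratio is infinite")
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return odds, float(p)


def _region_labels(
    region: GenomicInterval, cctcf_idx: IntervalIndex, nonconst_idx: IntervalIndex
) -> tuple[str, ...]:
    labels = []
    if cctcf_idx.overlaps_any(region):
        labels.append("cCTCF")
    if nonconst_idx.overlaps_any(region):
        labels.append("nonconst")
    return tuple(labels) if labels else ("neither",)


def fractional_type_counts(
    pairs: Sequence[InteractionPair],
    cctcf_sites: Sequence[GenomicInterval],
    nonconst_sites: Sequence[GenomicInterval],
) -> PairTypeCounts:
    """Distribute each pair's unit weight over its label combinations.

    Each region gets the set of distinct site labels it contains (or
    "neither"); the pair's weight 1 is split uniformly over the Cartesian
    product of the two label sets, accumulated as unordered label pairs.
    Label-set sizes are at most 2, so every split (1, 1/2, 1/4) is exact
    in binary floating point and the totals sum exactly to len(pairs).
    """
    cidx = IntervalIndex(cctcf_sites)
    nidx = IntervalIndex(nonconst_sites)
    counts = {t: 0.0 for t in PAIR_TYPES}
    for p in pairs:
        l1 = _region_labels(p.region1, cidx, nidx)
        l2 = _region_labels(p.region2, cidx, nidx)
        w = 1.0 / (len(l1) * len(l2))
        for x in l1:
            for y in l2:
                key = (x, y) if LABELS.index(x) <= LABELS.index(y) else (y, x)
                counts[key] += w
    return PairTypeCounts(counts, len(pairs))
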