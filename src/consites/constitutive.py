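"""Multi-cell-line occurrence aggregation and constitutive-site calling.

A binding site is "constitutive" when it is found in strictly more than a
threshold fraction (default 90%) of the surveyed cell lines.  Sites from
replicate experiments within one cell line collapse to a single
occurrence; a site's occurrence count is the number of distinct cell
lines containing it.  Site identity is exact (chrom, start, end, strand)
equality by default — best PWM hits on the same genomic motif instance
land on identical coordinates — with an optional fuzzy mode for noisy
real-world peak sets.

Constitutive CTCF sites are further classified against cohesin:

* ``cCTCF_cCohesin``    — also constitutive in both Rad21 and Smc3 peaks
* ``cCTCF_non_cohesin`` — overlapping no cohesin peak in any cell line
* ``cCTCF_other``       — everything in between (partial cohesin support)
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, IntervalIndex
from .pwm import BindingSite

__all__ = [
    "OccurrenceTable",
    "aggregate_sites",
    "min_required_count",
    "call_constitutive",
    "classify_sites",
    "CLASS_LABELS",
]

SiteIdentity = tuple  # (chrom, start, end, strand)

CLASS_LABELS = ("cCTCF_cCohesin", "cCTCF_non_cohesin", "cCTCF_other", "non_constitutive")


@dataclass
class OccurrenceTable:
    """Which cell lines contain each unique site."""

    entries: dict[SiteIdentity, set[str]] = field(default_factory=dict)
    n_cell_lines: int = 0

    def count(self, identity: SiteIdentity) -> int:
        return len(self.entries.get(identity, ()))

    def occurrence_histogram(self) -> dict[int, int]:
        """Number of sites found in exactly k cell lines, for each k."""
        hist: dict[int, int] = defaultdict(int)
        for lines in self.entries.values():
            hist[len(lines)] += 1
        return dict(hist)

    def write_tsv(self, path) -> None:
        """chrom, start, end, strand, number-of-cell-lines (tab-separated)."""
        with open(path, "w") as fh:
            for (chrom, start, end, strand), lines in sorted(self.entries.items()):
                fh.write(f"{chrom}\t{start}\t{end}\t{strand}\t{len(lines)}\n")


def _cluster_fuzzy(
    sites: list[tuple[SiteIdentity, str]], tolerance: int
) -> dict[SiteIdentity, set[str]]:
    """Single-linkage clustering of site identities within +-tolerance bp.

    Sites on the same chrom/strand are chained when consecutive starts
    differ by at most ``tolerance``; each cluster is keyed by its first
    member's coordinates.
    """
    by_key: dict[tuple[str, str], list[tuple[SiteIdentity, str]]] = defaultdict(list)
    for ident, line in sites:
        chrom, start, end, strand = ident
        by_key[(chrom, strand)].append((ident, line))
    entries: dict[SiteIdentity, set[str]] = {}
    for group in by_key.values():
        group.sort(key=lambda t: t[0][1])
        rep: SiteIdentity | None = None
        prev_start = None
        for ident, line in group:
            start = ident[1]
            if rep is None or start - prev_start > tolerance:
                rep = ident
                entries[rep] = set()
            entries[rep].add(line)
            prev_start = start
    return entries


def aggregate_sites(
    per_dataset_sites: Iterable[tuple[str, Sequence[BindingSite | GenomicInterval]]],
    n_cell_lines: int | None = None,
    tolerance: int = 0,
) -> OccurrenceTable:
    """Collapse replicate datasets into a per-cell-line occurrence table.

    ``per_dataset_sites`` yields (cell_line, sites); multiple entries for
    one cell line are replicates and collapse to unique site identities.
    With ``tolerance`` > 0, sites within that many bp (same chrom/strand)
    are merged by single-linkage clustering before counting.
    """
    flat: list[tuple[SiteIdentity, str]] = []
    lines_seen: set[str] = set()
    for cell_line, sites in per_dataset_sites:
        lines_seen.add(cell_line)
        for s in sites:
            iv = s.interval if hasattr(s, "interval") else s
            flat.append((iv.identity(), cell_line))
    if tolerance > 0:
        entries = _cluster_fuzzy(flat, tolerance)
    else:
        entries = defaultdict(set)
        for ident, line in flat:
            entries[ident].add(line)
        entries = dict(entries)
    n = n_cell_lines if n_cell_lines is not None else len(lines_seen)
    return OccurrenceTable(entries=entries, n_cell_lines=n)


def min_required_count(n_cell_lines: int, fraction: float = 0.9) -> int:
    """Smallest integer count with count / n strictly greater than fraction."""
    return math.floor(n_cell_lines * fraction) + 1


def call_constitutive(table: OccurrenceTable, fraction: float = 0.9) -> set[SiteIdentity]:
    """Identities present in strictly more than ``fraction`` of cell lines."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if table.n_cell_lines == 0:
        raise ValueError("occurrence table has no cell lines")
    need = min_required_count(table.n_cell_lines, fraction)
    return {ident for ident, lines in table.entries.items() if len(lines) >= need}


def classify_sites(
    cctcf: set[SiteIdentity],
    crad21: set[SiteIdentity],
    csmc3: set[SiteIdentity],
    cohesin_peaks_by_cell_line: Mapping[str, Sequence[GenomicInterval]],
) -> dict[SiteIdentity, str]:
    """Partition constitutive CTCF sites by their cohesin support.

    ``crad21``/``csmc3`` are the constitutive CTCF-site identities found in
    Rad21 and Smc3 peaks (each evaluated with that protein's own cell-line
    count).  ``cohesin_peaks_by_cell_line`` holds every cohesin peak from
    every cell line, used for the "no cohesin anywhere" test, which is an
    interval-overlap test (site vs 200-bp peak), not identity.
    """
    all_cohesin = [iv for ivs in cohesin_peaks_by_cell_line.values() for iv in ivs]
    cohesin_idx = IntervalIndex(all_cohesin)

    labels: dict[SiteIdentity, str] = {}
    in_both = crad21 & csmc3
    for ident in cctcf:
        if ident in in_both:
            labels[ident] = "cCTCF_cCohesin"
            continue
        chrom, start, end, strand = ident
        if not cohesin_idx.overlaps_any(GenomicInterval(chrom, start, end, strand)):
            labels[ident] = "cCTCF_non_cohesin"
        else:
            labels[ident] = "cCTCF_other"
    return labels


def class_counts(labels: Mapping[SiteIdentity, str]) -> dict[str, int]:
    counts = {lab: 0 for lab in CLASS_LABELS[:3]}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    return counts
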