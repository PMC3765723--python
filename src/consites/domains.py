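"""Placement of sites and interactions relative to topological domains.

Topological domains (from Hi-C) are non-overlapping megabase-scale
intervals.  Sites and interaction regions are assigned to the domain
containing their midpoint.  Distances to the nearest domain boundary are
standardized to the median domain length — a site d bp from the boundary
of a domain of length L reports d * median / L — so boundary-proximity
densities are comparable across domain sizes.  The density itself is a
Gaussian KDE (Silverman bandwidth) with reflection at zero.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .chiapet import InteractionPair
from .intervals import GenomicInterval

__all__ = [
    "TopologicalDomain",
    "BoundaryDistance",
    "DomainSet",
    "assign_domain",
    "classify_interactions_by_domain",
    "boundary_distance",
    "kde_distances",
]


@dataclass(frozen=True)
class TopologicalDomain:
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length


class DomainSet:
    """Sorted, validated domain intervals with point-assignment queries."""

    def __init__(self, domains: Sequence[TopologicalDomain | GenomicInterval]):
        self.domains = [
            d if isinstance(d, TopologicalDomain) else TopologicalDomain(d) for d in domains
        ]
        by_chrom: dict[str, list[TopologicalDomain]] = defaultdict(list)
        for d in self.domains:
            by_chrom[d.interval.chrom].append(d)
        self._by_chrom = {}
        for chrom, ds in by_chrom.items():
            ds.sort(key=lambda d: d.interval.start)
            for prev, cur in zip(ds, ds[1:]):
                if cur.interval.start < prev.interval.end:
                    raise ValueError(f"overlapping domains on {chrom}")
            starts = np.array([d.interval.start for d in ds])
            ends = np.array([d.interval.end for d in ds])
            self._by_chrom[chrom] = (starts, ends, ds)

    @property
    def median_length(self) -> float:
        return float(np.median([d.length for d in self.domains]))

    @property
    def mean_length(self) -> float:
        return float(np.mean([d.length for d in self.domains]))

    def containing(self, chrom: str, pos: int) -> TopologicalDomain | None:
        got = self._by_chrom.get(chrom)
        if got is None:
            return None
        starts, ends, ds = got
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and ends[i] > pos:
            return ds[i]
        return None


def assign_domain(
    x: GenomicInterval, domains: "DomainSet | Sequence"
) -> TopologicalDomain | None:
    """The unique domain containing x's midpoint, or None."""
    ds = domains if isinstance(domains, DomainSet) else DomainSet(domains)
    return ds.containing(x.chrom, x.midpoint)


@dataclass(frozen=True)
class BoundaryDistance:
    raw: float  # bp to the nearest boundary of the containing domain
    standardized: float  # raw rescaled to the median domain length


def boundary_distance(
    site: GenomicInterval, domain: TopologicalDomain, median_length: float
) -> BoundaryDistance:
    """Distance from the site midpoint to the nearest domain boundary.

    Standardized as raw * median_length / domain_length, i.e. the distance
    the site would have if its domain were median-sized.
    """
    mid = site.midpoint
    iv = domain.interval
    raw = float(min(mid - iv.start, iv.end - mid))
    if raw < 0:
        raise ValueError("site midpoint lies outside the domain")
    return BoundaryDistance(raw, raw * median_length / domain.length)


def classify_interactions_by_domain(
    pairs: Sequence[InteractionPair], domains: "DomainSet | Sequence"
) -> dict:
    """Per-pair domain placement and the headline fractions.

    Labels: same-domain / cross-domain (both region midpoints inside
    domains), partly-outside (one inside), outside (neither).  Same- vs
    cross-domain is only meaningful for intra-chromosomal pairs; the
    same-domain fraction is computed over intra-chromosomal pairs with
    both regions in domains.
    """
    ds = domains if isinstance(domains, DomainSet) else DomainSet(domains)
    labels: list[str] = []
    n_both_in = n_same = n_intra_both = 0
    for p in pairs:
        d1 = ds.containing(p.region1.chrom, p.region1.midpoint)
        d2 = ds.containing(p.region2.chrom, p.region2.midpoint)
        if d1 is None and d2 is None:
            labels.append("outside")
        elif d1 is None or d2 is None:
            labels.append("partly-outside")
        else:
            n_both_in += 1
            if p.region1.chrom == p.region2.chrom:
                n_intra_both += 1
                if d1 is d2:
                    n_same += 1
                    labels.append("same-domain")
                else:
                    labels.append("cross-domain")
            else:
                labels.append("cross-domain")
    return {
        "labels": labels,
        "fraction_both_in_domains": n_both_in / len(pairs) if pairs else float("nan"),
        "fraction_same_domain": n_same / n_intra_both if n_intra_both else float("nan"),
    }


def kde_distances(
    distances: Sequence[float], grid_points: int = 512, bw_method="silverman"
) -> dict:
    """Gaussian KDE of standardized boundary distances, reflected at 0.

    Returns the evaluation grid, the density, and the mode (grid argmax).
    Degenerate all-equal input yields a delta-like answer with a warning.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two distances")
    if np.ptp(d) == 0:
        warnings.warn("all distances identical; density is a point mass")
        grid = np.linspace(0, max(d[0] * 2, 1.0), grid_points)
        dens = np.zeros_like(grid)
        dens[int(np.argmin(np.abs(grid - d[0])))] = 1.0
        return {"grid": grid, "density": dens, "mode": float(d[0])}
    kde = stats.gaussian_kde(d, bw_method=bw_method)
    grid = np.linspace(0.0, float(d.max()), grid_points)
    dens = kde(grid) + kde(-grid)  # reflect mass that would fall below 0
    mode = float(grid[int(np.argmax(dens))])
    return {"grid": grid, "density": dens, "mode": mode}
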