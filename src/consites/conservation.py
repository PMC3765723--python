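"""Cross-species conservation of binding sites via alignment-block scanning.

For each site, the multiple-alignment block covering the 16-bp site plus
10 bp of flank is scanned species by species: each species' row is
gap-stripped and scored on both strands with the same PWM and p-value
cutoff used to call the site.  The number of species with at least one
passing window is the conservation statistic — no phylogenetic model,
just a count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .pwm import PWMModel, ScoreDistribution, exact_pvalue_table, scan_sequence

__all__ = [
    "AlignmentBlock",
    "read_maf",
    "write_maf",
    "merge_blocks",
    "species_with_hit",
    "conservation_summary",
]


@dataclass
class AlignmentBlock:
    """One multiple-alignment block keyed by species name.

    ``rows`` maps species -> gapped sequence; all rows share one length.
    The reference species' ungapped coordinates are ``ref_interval``.
    """

    ref_interval: GenomicInterval
    ref_species: str
    rows: dict[str, str]
    index: int = 0

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("gapped rows differ in length")
        if self.ref_species not in self.rows:
            raise ValueError(f"reference species {self.ref_species!r} missing from rows")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def read_maf(path, ref_species: str) -> list[AlignmentBlock]:
    """Read MAF alignment blocks (standard 'a'/'s' lines).

    Species are taken as the part of the MAF source name before the first
    '.', the remainder (if any) being the chromosome.
    """
    blocks: list[AlignmentBlock] = []
    for i, msa in enumerate(AlignIO.parse(str(path), "maf")):
        rows: dict[str, str] = {}
        ref_iv = None
        for rec in msa:
            species, _, chrom = rec.id.partition(".")
            rows[species] = str(rec.seq).upper()
            if species == ref_species:
                start = rec.annotations.get("start", 0)
                size = rec.annotations.get("size", len(str(rec.seq).replace("-", "")))
                strand = "+" if rec.annotations.get("strand", 1) == 1 else "-"
                ref_iv = GenomicInterval(chrom or species, start, start + size, strand)
        if ref_iv is None:
            raise ValueError(f"block {i} in {path} has no row for {ref_species!r}")
        blocks.append(AlignmentBlock(ref_iv, ref_species, rows, index=i))
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path) -> None:
    msas = []
    for blk in blocks:
        recs = []
        for species, seq in blk.rows.items():
            ungapped = len(seq) - seq.count("-")
            if species == blk.ref_species:
                rec = SeqRecord(Seq(seq), id=f"{species}.{blk.ref_interval.chrom}")
                rec.annotations = {
                    "start": blk.ref_interval.start,
                    "size": ungapped,
                    "strand": 1 if blk.ref_interval.strand != "-" else -1,
                    "srcSize": blk.ref_interval.end + 10_000,
                }
            else:
                rec = SeqRecord(Seq(seq), id=f"{species}.contig")
                rec.annotations = {"start": 0, "size": ungapped, "strand": 1,
                                   "srcSize": max(ungapped, 1)}
            recs.append(rec)
        msas.append(MultipleSeqAlignment(recs))
    AlignIO.write(msas, str(path), "maf")


def merge_blocks(blocks: Sequence[AlignmentBlock]) -> AlignmentBlock:
    """Concatenate consecutive blocks covering one query interval.

    Blocks must be sorted by reference coordinate and non-overlapping on
    the reference.  A species absent from a block is filled with gaps for
    that block's width, so every merged row has equal length.
    """
    if not blocks:
        raise ValueError("no blocks to merge")
    if len(blocks) == 1:
        return blocks[0]
    ref_sp = blocks[0].ref_species
    prev_end = None
    for blk in blocks:
        if blk.ref_species != ref_sp:
            raise ValueError("blocks disagree on the reference species")
        iv = blk.ref_interval
        if prev_end is not None:
            if iv.start < prev_end:
                raise ValueError("blocks overlap on the reference")
        prev_end = iv.end
    species = []
    seen = set()
    for blk in blocks:
        for sp in blk.rows:
            if sp not in seen:
                seen.add(sp)
                species.append(sp)
    rows = {
        sp: "".join(blk.rows.get(sp, "-" * blk.width) for blk in blocks)
        for sp in species
    }
    first, last = blocks[0].ref_interval, blocks[-1].ref_interval
    merged_iv = GenomicInterval(first.chrom, first.start, last.end, first.strand)
    return AlignmentBlock(merged_iv, ref_sp, rows, index=blocks[0].index)


def species_with_hit(
    block: AlignmentBlock,
    pwm: PWMModel,
    pvalue_cutoff: float = 0.0005,
    table: ScoreDistribution | None = None,
) -> int:
    """Number of species whose gap-stripped row has a passing PWM window.

    Both strands are scanned.  Rows shorter than the PWM width after gap
    removal (including all-gap rows) cannot hit and count as absent.
    """
    if table is None:
        table = exact_pvalue_table(pwm)
    threshold = table.score_threshold(pvalue_cutoff)
    n = 0
    for seq in block.rows.values():
        stripped = seq.replace("-", "")
        if len(stripped) < pwm.width:
            continue
        fwd, rev = scan_sequence(pwm, stripped)
        if max(fwd.max(initial=-np.inf), rev.max(initial=-np.inf)) >= threshold:
            n += 1
    return n


def conservation_summary(counts_by_class: dict[str, Sequence[int]]) -> dict[str, dict]:
    """Five-number summary + mean of species counts per site class."""
    out = {}
    for cls, counts in counts_by_class.items():
        arr = np.asarray(counts, dtype=float)
        if arr.size == 0:
            raise ValueError(f"class {cls!r} has no counts")
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[cls] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "min": float(arr.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(arr.max()),
            "counts": arr,
        }
    return out
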