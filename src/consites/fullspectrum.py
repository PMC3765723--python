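"""Full-spectrum motif discovery by positional k-mer counting.

The canonical CTCF core motif is 16 bp, but CTCF footprints can cover
40+ bp.  To look for flanking signal, each site is extended by 30 bp on
each side (76 bp total, minus-strand sites reverse-complemented so the
core always reads on the plus orientation).  At each of the
30+30+16-5+1 = 72 k-mer start positions we count, per 5-mer, the number
of sequences carrying that word at that position (presence, 0/1 per
sequence).  The top-ranked k-mers on each side of the core are then
blended — weighted by their position-specific counts — into a composite
base-weight matrix for that side.  Composites can be scored like PWMs to
measure how prevalent the extended motif is in each site class.

Side convention: "left" covers k-mers starting at offsets 0..flank-1,
"right" those starting at offsets flank+core..L-k; words starting inside
the core belong to neither side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval
from .pwm import PWMModel, encode, exact_pvalue_table, reverse_complement

__all__ = [
    "PositionalKmerCounts",
    "CompositeMotif",
    "extract_extended_sequences",
    "positional_kmer_counts",
    "build_composite_motif",
    "motif_prevalence",
]

BASES = "ACGT"


def kmer_to_string(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass
class PositionalKmerCounts:
    """positions x 4^k presence counts across a set of aligned sequences."""

    k: int
    counts: np.ndarray  # (L - k + 1, 4^k), uint32
    n_sequences: int
    core_width: int = 16
    flank: int = 30

    @property
    def positions(self) -> int:
        return self.counts.shape[0]

    def side_positions(self, side: str) -> range:
        """K-mer start offsets belonging to one flank."""
        if side == "left":
            return range(0, self.flank)
        if side == "right":
            return range(self.flank + self.core_width, self.positions)
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass
class CompositeMotif:
    """A flank motif built from weighted top k-mers.

    ``matrix`` columns cover genomic offsets ``offset_start`` ..
    ``offset_start + width - 1`` of the extended (76-bp) window and each
    normalizes to 1.  ``contributing_kmers`` lists (kmer string, rank
    statistic) for the words that were blended in.
    """

    side: str
    matrix: np.ndarray  # (width, 4), rows are positions (PWM orientation)
    offset_start: int
    contributing_kmers: list[tuple[str, int]]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def to_pwm(self, background=None, pseudocount: float = 0.001) -> PWMModel:
        return PWMModel(self.matrix, background, pseudocount)

    def trimmed(self, min_column_mass: float = 0.05) -> "CompositeMotif":
        """Drop weakly supported edge columns (pre-normalization mass).

        Emitting trimmed variants lets one composite be reported at more
        than one width (e.g. a 26-mer and its 20-mer core).
        """
        mass = getattr(self, "_column_mass", None)
        if mass is None:
            return self
        keep = np.nonzero(mass >= min_column_mass * mass.max())[0]
        if len(keep) == 0:
            return self
        lo, hi = int(keep[0]), int(keep[-1]) + 1
        out = CompositeMotif(
            self.side, self.matrix[lo:hi], self.offset_start + lo, self.contributing_kmers
        )
        out._column_mass = mass[lo:hi]
        return out

    def write_pfm(self, path) -> None:
        """JASPAR-style 4-row position frequency matrix."""
        with open(path, "w") as fh:
            fh.write(f"># composite {self.side} flank, offsets {self.offset_start}+\n")
            for b, base in enumerate(BASES):
                row = " ".join(f"{v:.4f}" for v in self.matrix[:, b])
                fh.write(f"{base} [ {row} ]\n")


def extract_extended_sequences(
    sites: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    flank: int = 30,
) -> list[str]:
    """Core ± flank sequence for each site, core-oriented.

    ``genome`` is any mapping chrom -> sequence string (a dict, a
    pyfaidx.Fasta via str(), or the synthetic Genome).  Minus-strand sites
    are reverse-complemented so the core motif reads on the forward
    orientation.  Sites too close to a contig edge are skipped with a
    warning.
    """
    out: list[str] = []
    skipped = 0
    for site in sites:
        chrom_seq = genome[site.chrom]
        lo = site.start - flank
        hi = site.end + flank
        if lo < 0 or hi > len(chrom_seq):
            skipped += 1
            continue
        seq = str(chrom_seq[lo:hi]).upper()
        if site.strand == "-":
            seq = reverse_complement(seq)
        out.append(seq)
    if skipped:
        warnings.warn(f"skipped {skipped} site(s) too close to a contig edge")
    return out


def positional_kmer_counts(
    seqs: Sequence[str], k: int = 5, core_width: int = 16, flank: int = 30
) -> PositionalKmerCounts:
    """Presence count of each k-mer at each start position.

    Each sequence contributes 0/1 per (position, k-mer) cell; windows
    containing N contribute nothing.
    """
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must all have the same length")
    if L < k:
        raise ValueError(f"sequences shorter than k={k}")
    n_pos = L - k + 1
    counts = np.zeros((n_pos, 4 ** k), dtype=np.uint32)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    pos_idx = np.arange(n_pos)
    for seq in seqs:
        codes = encode(seq).astype(np.int64)
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        ok = (win <= 3).all(axis=1)
        kcodes = (np.where(win <= 3, win, 0) @ weights)
        np.add.at(counts, (pos_idx[ok], kcodes[ok]), 1)
    return PositionalKmerCounts(k, counts, len(seqs), core_width, flank)


def build_composite_motif(
    counts: PositionalKmerCounts, side: str, top_n: int = 50
) -> CompositeMotif:
    """Blend the side's top-ranked k-mers into a composite base-weight matrix.

    K-mers are ranked by their maximum single-position presence count
    within the side (positional specificity, not total abundance).  Each
    selected k-mer deposits, at every side position, its positional count
    onto the bases it spells at the covered offsets; columns are then
    normalized to probabilities.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    pos_range = counts.side_positions(side)
    sub = counts.counts[list(pos_range)]  # (n_side_pos, 4^k)
    peak_count = sub.max(axis=0)  # per k-mer max over side positions
    present = np.nonzero(peak_count > 0)[0]
    if len(present) < top_n:
        warnings.warn(
            f"only {len(present)} distinct k-mers present on the {side} side; using all"
        )
        top = present[np.argsort(peak_count[present])[::-1]]
    else:
        order = np.argsort(peak_count, kind="stable")[::-1]
        top = order[:top_n]

    k = counts.k
    offset_start = pos_range.start
    width = (pos_range.stop - 1) + k - offset_start  # last window end - first start
    weights = np.zeros((width, 4))
    for code in top:
        word = kmer_to_string(int(code), k)
        word_codes = encode(word)
        for p_i, pos in enumerate(pos_range):
            w = float(sub[p_i, code])
            if w == 0:
                continue
            for j in range(k):
                weights[pos - offset_start + j, word_codes[j]] += w

    col_mass = weights.sum(axis=1)
    matrix = np.empty_like(weights)
    zero = col_mass == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} composite column(s) had no support; set uniform")
    matrix[zero] = 0.25
    matrix[~zero] = weights[~zero] / col_mass[~zero, None]
    kmers = [(kmer_to_string(int(c), k), int(peak_count[c])) for c in top]
    out = CompositeMotif(side, matrix, offset_start, kmers)
    out._column_mass = col_mass
    return out


def motif_prevalence(
    site_class_seqs: Mapping[str, Sequence[str]],
    motifs: Mapping[str, "CompositeMotif | PWMModel"],
    score_cutoff_pvalue: float = 0.0005,
    core_offset: int = 30,
) -> dict[str, dict[str, float]]:
    """Fraction of each class's extended sequences matching each motif.

    Motifs are anchored at their fixed offsets within the extended window
    (composites know theirs; a bare core PWM is anchored at
    ``core_offset``) and scored forward-strand only, since the sequences
    are already core-oriented.  A sequence matches when its anchored score
    reaches the motif's exact-p-value cutoff.
    """
    results: dict[str, dict[str, float]] = {}
    prepared = []
    for name, m in motifs.items():
        if isinstance(m, CompositeMotif):
            pwm, off = m.to_pwm(), m.offset_start
        else:
            pwm, off = m, core_offset
        thr = exact_pvalue_table(pwm).score_threshold(score_cutoff_pvalue)
        lom = pwm.log_odds()
        prepared.append((name, lom, off, pwm.width, thr))

    for cls, seqs in site_class_seqs.items():
        if not seqs:
            raise ValueError(f"site class {cls!r} has no sequences")
        results[cls] = {}
        for name, lom, off, w, thr in prepared:
            hits = 0
            idx = np.arange(w)
            for seq in seqs:
                window = seq[off : off + w]
                if len(window) < w:
                    continue
                codes = encode(window)
                if (codes > 3).any():
                    continue
                if float(lom[idx, codes].sum()) >= thr:
                    hits += 1
            results[cls][name] = hits / len(seqs)
    return results
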