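"""Position weight matrix scoring with exact score-distribution p-values.

A PWM is scored as log-odds against a background model:

    score(s) = sum_i [ log(p_i(s_i) + pc) - log(bg(s_i) + pc) ]

with a small pseudocount ``pc`` so zero matrix entries stay finite.  The
p-value of a score is the exact tail probability P(score >= s) over all
width-length sequences drawn from the background, computed by dynamic
programming on a discretized score lattice (convolution of the
per-position score distributions).  Windows containing N are invalid and
never called.

The site-calling rule mirrors standard ChIP-seq practice: within each
peak, both strands are scanned at every offset and the single
highest-scoring window is the binding site, provided its p-value passes
the cutoff (default 5e-4).  Because the p-value is monotone in the score,
"best window passing the cutoff" equals "best window, if it passes".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval, Peak

__all__ = [
    "PWMModel",
    "BindingSite",
    "ScoreDistribution",
    "read_pwm",
    "score_window",
    "exact_pvalue_table",
    "scan_sequence",
    "best_site_in_peak",
    "best_sites_in_peaks",
    "reverse_complement",
]

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to codes 0..3 (A,C,G,T); anything else -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWMModel:
    """A width x 4 base-probability matrix with a background model."""

    probs: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray = None  # (4,)
    pseudocount: float = 0.001

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        bg = self.background
        bg = np.full(4, 0.25) if bg is None else np.asarray(bg, dtype=float)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be a (width, 4) matrix with width >= 1")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) log-odds matrix: log(p+pc) - log(bg+pc)."""
        pc = self.pseudocount
        with np.errstate(divide="ignore"):  # pc=0 with a zero entry -> -inf, by design
            return np.log(self.probs + pc) - np.log(self.background + pc)[None, :]

    def log_odds_revcomp(self) -> np.ndarray:
        """Log-odds for scoring the reverse complement in forward coordinates."""
        return self.log_odds()[::-1, ::-1]

    @classmethod
    def from_counts(cls, counts, background=None, pseudocount: float = 0.001) -> "PWMModel":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(probs, background, pseudocount)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))


@dataclass(frozen=True)
class BindingSite:
    """The best PWM hit inside one peak."""

    interval: GenomicInterval  # length == pwm width; strand = scan strand
    score: float
    pvalue: float
    cell_line: str = ""
    dataset: str = ""

    def identity(self) -> tuple:
        return self.interval.identity()


def read_pwm(path, background=None, pseudocount: float = 0.001) -> PWMModel:
    """Read a plain-text PWM: one row per position, columns A C G T.

    Rows may be counts or probabilities; counts are normalized.  Lines
    starting with '#' or '>' are ignored.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", ">")):
            continue
        rows.append([float(x) for x in line.split()])
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (A C G T), got shape {mat.shape}")
    return PWMModel.from_counts(mat, background, pseudocount)


def write_pwm(pwm: PWMModel, path) -> None:
    np.savetxt(path, pwm.probs, fmt="%.6f", header="A C G T")


def score_window(pwm: PWMModel, seq: str, strand: str = "+") -> float:
    """Log-odds score of one window; -inf if the window contains N."""
    if len(seq) != pwm.width:
        raise ValueError(f"sequence length {len(seq)} != PWM width {pwm.width}")
    if strand == "-":
        seq = reverse_complement(seq)
    codes = encode(seq)
    if (codes > 3).any():
        return float("-inf")
    return float(pwm.log_odds()[np.arange(pwm.width), codes].sum())


@dataclass
class ScoreDistribution:
    """Exact discretized tail distribution of PWM scores under background.

    ``bins`` are integer multiples of ``granularity`` (ascending);
    ``tail[i]`` = P(discretized score >= bins[i] * granularity).
    """

    granularity: float
    bins: np.ndarray  # int64, ascending
    tail: np.ndarray  # float, non-increasing

    def pvalue(self, score: float) -> float:
        if score == float("-inf"):
            return 1.0
        k = int(round(score / self.granularity))
        i = int(np.searchsorted(self.bins, k, side="left"))
        if i >= len(self.bins):
            return 0.0
        return float(self.tail[i])

    def score_threshold(self, pvalue_cutoff: float) -> float:
        """Smallest achievable score whose p-value is <= the cutoff.

        Returns +inf if no achievable score passes.
        """
        passing = np.nonzero(self.tail <= pvalue_cutoff)[0]
        if len(passing) == 0:
            return float("inf")
        # tail is non-increasing, so the first passing index is the smallest score
        return float(self.bins[passing[0]]) * self.granularity


def exact_pvalue_table(pwm: PWMModel, granularity: float = 1e-3) -> ScoreDistribution:
    """Exact PWM score distribution by per-position convolution.

    Each position contributes one of four discretized scores with its
    background probability; the total-score distribution is the convolution
    of the per-position distributions, exact up to the discretization.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    lom = pwm.log_odds()
    keys = np.rint(lom / granularity).astype(np.int64)  # (width, 4)
    bg = pwm.background

    lo = int(keys.min(axis=1).sum())
    hi = int(keys.max(axis=1).sum())
    probs = np.zeros(hi - lo + 1)
    # dist over offset-encoded bins; start with the identity (score 0)
    dist = np.array([1.0])
    off = 0  # bin value of dist[0]
    for i in range(pwm.width):
        ks = keys[i]
        new_lo = off + int(ks.min())
        new_hi = off + len(dist) - 1 + int(ks.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            sh = off + int(ks[b]) - new_lo
            new[sh : sh + len(dist)] += dist * bg[b]
        dist, off = new, new_lo
    probs[off - lo : off - lo + len(dist)] = dist

    nz = np.nonzero(probs > 0)[0]
    bins = (nz + lo).astype(np.int64)
    mass = probs[nz]
    tail = np.cumsum(mass[::-1])[::-1]
    # guard against cumulative rounding above 1
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(granularity, bins, tail)


def scan_sequence(pwm: PWMModel, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Score every window of ``seq`` on both strands.

    Returns (fwd, rev) arrays of length len(seq) - width + 1; index i is
    the window starting at i.  Windows containing N score -inf.
    """
    w = pwm.width
    codes = encode(seq)
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0)
    valid_base = codes <= 3
    safe = np.where(valid_base, codes, 0)
    lom_f = pwm.log_odds()
    lom_r = pwm.log_odds_revcomp()
    win = np.lib.stride_tricks.sliding_window_view(safe, w)  # (n_win, w)
    idx = np.arange(w)
    fwd = lom_f[idx, win].sum(axis=1)
    rev = lom_r[idx, win].sum(axis=1)
    ok = np.lib.stride_tricks.sliding_window_view(valid_base, w).all(axis=1)
    fwd = np.where(ok, fwd, -np.inf)
    rev = np.where(ok, rev, -np.inf)
    return fwd, rev


def best_sites_in_peaks(
    pwm: PWMModel,
    peaks,
    genome,
    pvalue_cutoff: float = 0.0005,
    table: ScoreDistribution | None = None,
    chunk_size: int = 2048,
) -> list:
    """Vectorized ``best_site_in_peak`` over many peaks.

    ``genome`` maps chrom -> sequence string.  Returns one BindingSite or
    None per peak, in input order; equivalent to calling
    ``best_site_in_peak`` on each peak but batched for throughput.
    """
    from collections import defaultdict

    if table is None:
        table = exact_pvalue_table(pwm)
    threshold = table.score_threshold(pvalue_cutoff)
    w = pwm.width
    lom_f = pwm.log_odds()
    lom_r = pwm.log_odds_revcomp()
    idx_w = np.arange(w)
    results: list = [None] * len(peaks)
    by_len: dict[int, list[int]] = defaultdict(list)
    for i, p in enumerate(peaks):
        by_len[p.interval.length].append(i)
    for L, idxs in by_len.items():
        if L < w:
            continue
        for c0 in range(0, len(idxs), chunk_size):
            sub = idxs[c0 : c0 + chunk_size]
            codes = np.empty((len(sub), L), dtype=np.uint8)
            for r, i in enumerate(sub):
                iv = peaks[i].interval
                codes[r] = encode(str(genome[iv.chrom][iv.start : iv.end]).upper())
            valid = codes <= 3
            safe = np.where(valid, codes, 0)
            win = np.lib.stride_tricks.sliding_window_view(safe, w, axis=1)
            fwd = lom_f[idx_w, win].sum(axis=-1)
            rev = lom_r[idx_w, win].sum(axis=-1)
            ok = np.lib.stride_tricks.sliding_window_view(valid, w, axis=1).all(axis=-1)
            fwd = np.where(ok, fwd, -np.inf)
            rev = np.where(ok, rev, -np.inf)
            comb = np.maximum(fwd, rev)
            best = comb.max(axis=1)
            pos = comb.argmax(axis=1)
            for r, i in enumerate(sub):
                if not np.isfinite(best[r]) or best[r] < threshold:
                    continue
                po = int(pos[r])
                strand = "+" if fwd[r, po] >= rev[r, po] else "-"
                score = float(fwd[r, po] if strand == "+" else rev[r, po])
                p = peaks[i]
                iv = p.interval
                site_iv = GenomicInterval(iv.chrom, iv.start + po, iv.start + po + w, strand)
                results[i] = BindingSite(
                    site_iv, score, table.pvalue(score), p.source_cell_line, p.source_dataset
                )
    return results


def best_site_in_peak(
    pwm: PWMModel,
    peak_seq: str,
    peak: Peak,
    pvalue_cutoff: float = 0.0005,
    table: ScoreDistribution | None = None,
) -> BindingSite | None:
    """Call the single best-scoring site in a peak, or None.

    Both strands are scanned at every offset; the maximal-score window
    passing the p-value cutoff wins.  Ties break leftmost, then '+'.
    ``table`` may be passed to reuse a precomputed score distribution.
    """
    if len(peak_seq) < pwm.width:
        return None
    if table is None:
        table = exact_pvalue_table(pwm)
    fwd, rev = scan_sequence(pwm, peak_seq)
    combined = np.maximum(fwd, rev)
    best = combined.max()
    if best == -np.inf or table.pvalue(float(best)) > pvalue_cutoff:
        return None
    pos = int(np.argmax(combined))  # first occurrence == leftmost
    strand = "+" if fwd[pos] >= rev[pos] else "-"
    score = float(fwd[pos] if strand == "+" else rev[pos])
    iv = peak.interval
    site_iv = GenomicInterval(iv.chrom, iv.start + pos, iv.start + pos + pwm.width, strand)
    return BindingSite(
        interval=site_iv,
        score=score,
        pvalue=table.pvalue(score),
        cell_line=peak.source_cell_line,
        dataset=peak.source_dataset,
    )
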