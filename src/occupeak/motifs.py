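"""PWM scanning with exact null score distributions, and motif enrichment.

Scoring is the standard log-likelihood ratio in bits against a background
base composition.  Scores are discretized to a 1/1000-bit grid (integer
"millibits") both when scanning and when building the null distribution, so
the dynamic-programming tail probability P(score >= s) for a random
background width-mer is *exact* on that grid — the same construction FIMO
uses to attach p-values to occurrences.  Enrichment of occurrences inside
peaks versus the whole genome is a hypergeometric test over scannable
window start positions (both strands), BH-corrected across motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import TssProfile, tss_profile
from .intervals import GenomicInterval, GeneModel
from .stats import EnrichmentResult, bh_adjust, hypergeom_upper_tail

GRID = 1000  # millibits per bit

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

BASES = "ACGT"


@dataclass
class PWM:
    """A motif probability matrix with background frequencies.

    matrix : (width, 4) per-position probabilities over A, C, G, T.
    background : length-4 background probabilities.
    pseudocount : probability mass added per cell before taking log-odds
        (cells become (p + c) / (1 + 4c)).
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (width, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self._dist_cache: tuple[int, np.ndarray] | None = None

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def int_matrix(self) -> np.ndarray:
        """Log-odds scores in integer millibits, shape (width, 4)."""
        c = self.pseudocount
        adj = (self.matrix + c) / (1.0 + 4.0 * c)
        with np.errstate(divide="ignore"):
            bits = np.log2(adj / self.background)
        ints = np.where(np.isneginf(bits), -(10**7), np.rint(bits * GRID))
        return ints.astype(np.int64)

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.name,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )

    # -- exact null distribution ------------------------------------------

    def _distribution(self) -> tuple[int, np.ndarray]:
        """(lowest integer score, probability mass per grid point) for a
        random background width-mer."""
        if self._dist_cache is not None:
            return self._dist_cache
        I = self.int_matrix
        cur = np.array([1.0])
        cur_lo = 0
        for i in range(self.width):
            col = I[i]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(len(cur) + (hi - lo))
            for j in range(4):
                off = int(col[j]) - lo
                new[off : off + len(cur)] += cur * self.background[j]
            cur = new
            cur_lo += lo
        self._dist_cache = (cur_lo, cur)
        return self._dist_cache

    def _tail(self) -> tuple[int, np.ndarray]:
        """(lowest integer score, P(S >= s) for each grid point s)."""
        lo, dist = self._distribution()
        return lo, np.cumsum(dist[::-1])[::-1]


@dataclass(frozen=True)
class MotifHit:
    motif: str
    interval: GenomicInterval
    score: float  # bits
    pvalue: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("pvalue must be in (0, 1]")


def score_window(pwm: PWM, sequence: str) -> float:
    """Log-odds score (bits) of one width-length window.

    Returns -inf for windows containing N; raises on other non-ACGT
    characters.
    """
    if len(sequence) != pwm.width:
        raise ValueError(
            f"sequence length {len(sequence)} != motif width {pwm.width}"
        )
    seq = sequence.upper()
    if any(ch not in "ACGTN" for ch in seq):
        raise ValueError(f"non-DNA characters in {sequence!r}")
    if "N" in seq:
        return float("-inf")
    I = pwm.int_matrix
    total = sum(int(I[i, "ACGT".index(ch)]) for i, ch in enumerate(seq))
    return total / GRID


def score_pvalue(pwm: PWM, score: float) -> float:
    """Exact tail probability P(S >= score) for a random background
    width-mer, on the 1/1000-bit grid.

    Scores below the minimum achievable give 1.0; scores above the maximum
    give the probability mass of the maximum (a positive floor, since
    reported p-values stay in (0, 1]).
    """
    lo, tail = pwm._tail()
    t = math.ceil(score * GRID - 1e-9)
    if t <= lo:
        return 1.0
    hi = lo + len(tail) - 1
    if t > hi:
        return float(max(tail[-1], 1e-300))
    return float(max(tail[t - lo], 1e-300))


def _int_threshold(pwm: PWM, pvalue_cutoff: float) -> int:
    """Smallest integer score with tail probability < cutoff."""
    lo, tail = pwm._tail()
    below = np.flatnonzero(tail < pvalue_cutoff)
    if len(below) == 0:
        return lo + len(tail)  # unreachable: no score is significant
    return lo + int(below[0])


def _scan_scores(int_matrix: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Integer scores for every window start (invalid windows = INT_MIN)."""
    w = int_matrix.shape[0]
    L = len(codes)
    n = L - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    safe = np.where(codes < 4, codes, 0)
    for i in range(w):
        scores += int_matrix[i][safe[i : i + n]]
    badcum = np.concatenate([[0], np.cumsum(codes >= 4)])
    invalid = (badcum[w:] - badcum[:-w]) > 0
    scores[invalid] = np.iinfo(np.int64).min
    return scores


def scan(
    pwm: PWM,
    genome: Mapping[str, str],
    regions: Sequence[GenomicInterval] | None = None,
    pvalue_cutoff: float = 1e-4,
) -> list[MotifHit]:
    """FIMO-style occurrence finding on both strands.

    The minus strand is scanned by scoring the reverse-complement matrix on
    the forward sequence, so a hit's interval is always given in forward
    coordinates and a palindromic instance yields hits on both strands at
    the same interval.  Windows containing N are skipped.  Restricted to
    ``regions`` when given (hits lie fully inside a region).
    """
    w = pwm.width
    lo, tail = pwm._tail()
    hi = lo + len(tail) - 1
    threshold = _int_threshold(pwm, pvalue_cutoff)
    fwd = pwm.int_matrix
    rev = fwd[::-1, ::-1]
    hits: list[MotifHit] = []

    def scan_block(chrom: str, seq: str, offset: int) -> None:
        codes = _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
        for mat, strand in ((fwd, "+"), (rev, "-")):
            scores = _scan_scores(mat, codes)
            for pos in np.flatnonzero(scores >= threshold):
                s = int(scores[pos])
                p = float(max(tail[min(s, hi) - lo], 1e-300))
                hits.append(
                    MotifHit(
                        pwm.name,
                        GenomicInterval(
                            chrom, offset + int(pos), offset + int(pos) + w, strand
                        ),
                        s / GRID,
                        p,
                    )
                )

    if regions is None:
        for chrom in sorted(genome):
            scan_block(chrom, genome[chrom], 0)
    else:
        for region in regions:
            seq = genome.get(region.chrom)
            if seq is None or region.end > len(seq):
                raise ValueError(
                    f"region {region.chrom}:{region.start}-{region.end} "
                    "outside genome"
                )
            scan_block(region.chrom, seq[region.start : region.end], region.start)
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def scannable_positions(lengths: Sequence[int], width: int) -> int:
    """Number of window start positions on both strands."""
    return 2 * sum(max(L - width + 1, 0) for L in lengths)


def motif_enrichment(
    name: str, k: int, n: int, K: int, N: int
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of in-peak motif occurrences.

    k of n scannable positions inside peaks are occurrences; K of N
    genome-wide positions are.  q is filled in by
    :func:`motif_enrichment_table` across all motifs tested.
    """
    p = hypergeom_upper_tail(k, K, n, N)
    return EnrichmentResult(name, k, K, n, N, p, q=1.0)


def motif_enrichment_table(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """BH adjustment across motifs; significance flag at q < alpha."""
    if not results:
        return []
    q = bh_adjust([r.p for r in results])
    return [
        EnrichmentResult(r.term, r.k, r.K, r.n, r.N, r.p, float(qi), bool(qi < alpha))
        for r, qi in zip(results, q)
    ]


def peaks_with_motif(
    peaks: Sequence[GenomicInterval], hits: Sequence[MotifHit]
) -> list[GenomicInterval]:
    """Peaks containing at least one hit (hit fully inside the peak)."""
    out = []
    for p in peaks:
        if any(
            h.interval.chrom == p.chrom
            and h.interval.start >= p.start
            and h.interval.end <= p.end
            for h in hits
        ):
            out.append(p)
    return out


def motif_tss_distribution(
    peaks: Sequence[GenomicInterval],
    hits: Sequence[MotifHit],
    genes: Sequence[GeneModel],
    window: int = 20_000,
    bin: int = 500,
) -> TssProfile:
    """TSS-distance profile restricted to motif-bearing peaks."""
    return tss_profile(peaks_with_motif(peaks, hits), genes, window, bin)


def write_hits(path, hits: Sequence[MotifHit]) -> None:
    with open(path, "w") as fh:
        fh.write("motif\tchrom\tstart\tend\tstrand\tscore\tpvalue\n")
        for h in hits:
            iv = h.interval
            fh.write(
                f"{h.motif}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{h.score:.3f}\t{h.pvalue:.4g}\n"
            )
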