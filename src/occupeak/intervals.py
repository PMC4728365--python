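"""Genomic interval data model and interval algebra.

All coordinates are 0-based half-open (BED convention).  The algebra here
(merge, pairwise overlap, nearest point) is deliberately small and
deterministic: it backs the consensus clustering, coincidence fractions and
TSS-distance profiles downstream, so every tie-break is pinned down.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


@dataclass(frozen=True)
class TagAlignment:
    """One aligned sequencing tag (single-end read).

    ``five_prime`` is the base that marks the sonicated fragment end: the
    interval start on the forward strand, ``end - 1`` on the reverse strand.
    """

    interval: GenomicInterval
    sample: str = "treatment"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("tag alignments must be stranded")
        if self.sample not in ("treatment", "control"):
            raise ValueError(f"unknown sample label {self.sample!r}")

    @property
    def five_prime(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass
class Track:
    """A named feature track (histone mark, CpG islands, FAIRE, ...)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def coverage(self) -> int:
        """Total merged base coverage of the track."""
        return sum(len(iv) for iv in merge_intervals(self.intervals))


@dataclass(frozen=True)
class GeneModel:
    """A transcript with strand-aware TSS/TES.

    For a forward-strand gene the TSS is ``start`` and the TES ``end - 1``;
    for a reverse-strand gene the TSS is ``end - 1`` and the TES ``start``.
    """

    interval: GenomicInterval
    name: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r} must be stranded")
        if len(self.interval) < 2:
            raise ValueError(f"gene {self.name!r}: TSS and TES must differ")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


def merge_intervals(
    ivs: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals separated by at most ``gap`` bases.

    Book-ended intervals ([a,b), [b,c)) merge at gap=0.  Output is sorted and
    pairwise non-overlapping; strand information is dropped (merged regions
    are unstranded).
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    ordered = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end, strand=".")
        else:
            merged.append(replace(iv, strand="."))
    return merged


def overlap_pairs(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[int, int]]:
    """All index pairs (i, j) where a[i] and b[j] overlap by >= min_overlap bases.

    Complete (no missed pairs); output sorted by (i, j).  A sweep over
    b sorted per chromosome keeps this near O((n+m) log m + hits).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for j, iv in enumerate(b):
        by_chrom[iv.chrom].append((iv.start, iv.end, j))
    max_len: dict[str, int] = {}
    for chrom, items in by_chrom.items():
        items.sort()
        max_len[chrom] = max(e - s for s, e, _ in items)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        items = by_chrom.get(iv.chrom)
        if not items:
            continue
        starts = [s for s, _, _ in items]
        # any overlapping b must start after iv.start - max_len
        lo = bisect_left(starts, iv.start - max_len[iv.chrom])
        for s, e, j in items[lo:]:
            if s >= iv.end - (min_overlap - 1):
                break
            if min(iv.end, e) - max(iv.start, s) >= min_overlap:
                pairs.append((i, j))
    pairs.sort()
    return pairs


def nearest_point(
    query: int, points: Sequence[tuple[int, object]]
) -> tuple[object, int]:
    """Nearest point to ``query``; returns (payload, signed distance).

    Signed distance = point position - query.  Ties in |distance| break
    toward the smaller coordinate.  ``points`` must be non-empty (the caller
    restricts to the query chromosome first).
    """
    if not points:
        raise ValueError("no point on chromosome")
    ordered = sorted(points, key=lambda p: p[0])
    positions = [p for p, _ in ordered]
    idx = bisect_left(positions, query)
    candidates = []
    if idx > 0:
        candidates.append(ordered[idx - 1])
    if idx < len(ordered):
        candidates.append(ordered[idx])
    # ties toward the smaller coordinate: candidates are in coordinate order,
    # so strict improvement keeps the earlier one
    best_pos, best_payload = candidates[0]
    for pos, payload in candidates[1:]:
        if abs(pos - query) < abs(best_pos - query):
            best_pos, best_payload = pos, payload
    return best_payload, best_pos - query
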