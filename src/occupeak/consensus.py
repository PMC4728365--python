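"""Multi-caller consensus peak sets and Venn accounting.

Cross-caller identity is single-linkage: peaks from any callers that overlap
by >= 1 bp belong to one cluster, transitively.  For intervals the
transitive closure of the overlap graph is exactly what a coordinate sweep
produces, so clustering is a sort plus one pass.  A cluster's interval is
the union span of its members; its support records which callers
contributed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .intervals import GenomicInterval
from .peakcalling import Peak


@dataclass(frozen=True)
class ConsensusPeak:
    interval: GenomicInterval
    support: frozenset[str]
    members: tuple[Peak, ...] = ()

    @property
    def n_support(self) -> int:
        return len(self.support)


@dataclass
class VennCounts:
    """Counts per region of the 3-set Venn diagram plus per-caller totals."""

    regions: dict[frozenset[str], int]
    totals: dict[str, int]

    def region(self, *callers: str) -> int:
        return self.regions.get(frozenset(callers), 0)

    @property
    def n_clusters(self) -> int:
        return sum(self.regions.values())


def cluster_peaks(peaksets: Sequence[Sequence[Peak]]) -> list[ConsensusPeak]:
    """Single-linkage clustering of peaks across callers by >= 1 bp overlap.

    Every input peak belongs to exactly one cluster.  Caller order is
    irrelevant to the resulting intervals.
    """
    allpeaks = [p for ps in peaksets for p in ps]
    allpeaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    clusters: list[ConsensusPeak] = []
    cur: list[Peak] = []
    cur_end = None
    for p in allpeaks:
        iv = p.interval
        if cur and iv.chrom == cur[0].interval.chrom and iv.start < cur_end:
            cur.append(p)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(_finish(cur))
            cur = [p]
            cur_end = iv.end
    if cur:
        clusters.append(_finish(cur))
    return clusters


def _finish(members: list[Peak]) -> ConsensusPeak:
    chrom = members[0].interval.chrom
    start = min(p.interval.start for p in members)
    end = max(p.interval.end for p in members)
    return ConsensusPeak(
        GenomicInterval(chrom, start, end),
        frozenset(p.caller for p in members),
        tuple(members),
    )


def select_consensus(
    clusters: Sequence[ConsensusPeak], min_support: int
) -> list[ConsensusPeak]:
    """Clusters supported by at least ``min_support`` callers, sorted.

    min_support=1 is the merged set, 2 the >=2-of-3 high-confidence set,
    3 the stringent set.
    """
    if not 1 <= min_support <= 3:
        raise ValueError("min_support must be in 1..3")
    out = [c for c in clusters if c.n_support >= min_support]
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return out


def venn_counts(
    clusters: Sequence[ConsensusPeak], callers: Sequence[str] | None = None
) -> VennCounts:
    """Tabulate the 7 Venn regions by exact support set, per cluster."""
    if callers is None:
        seen = sorted({c for cl in clusters for c in cl.support})
        callers = seen if seen else []
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(callers) + 1):
        for combo in combinations(sorted(callers), r):
            regions[frozenset(combo)] = 0
    counted = Counter(cl.support for cl in clusters)
    for support, n in counted.items():
        regions[frozenset(support)] = regions.get(frozenset(support), 0) + n
    totals = {
        c: sum(n for s, n in counted.items() if c in s) for c in sorted(callers)
    }
    return VennCounts(regions, totals)


def write_consensus(path, clusters: Sequence[ConsensusPeak]) -> None:
    """BED6: name = support-set string (e.g. poisson+threshold), score = n."""
    with open(path, "w") as fh:
        for c in clusters:
            iv = c.interval
            name = "+".join(sorted(c.support))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{c.n_support}\t.\n")


def write_venn(path, venn: VennCounts) -> None:
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        for support in sorted(venn.regions, key=lambda s: (len(s), sorted(s))):
            fh.write("+".join(sorted(support)) + f"\t{venn.regions[support]}\n")
        for caller, n in venn.totals.items():
            fh.write(f"total:{caller}\t{n}\n")
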