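"""Peak annotation relative to gene models.

Classifies each peak into one of six exclusive gene-relative categories,
profiles signed midpoint-to-TSS distances, and relates per-chromosome peak
counts to chromosome length.

Category windows are strand-aware.  For a forward-strand gene [s, e):
promoter = [s-5000, s), 3' downstream = [e, e+5000), far upstream =
[s-100000, s-5000), far downstream = [e+5000, e+100000); reverse-strand
genes mirror these around their TSS at e-1.  A peak qualifies on >= 1 bp
overlap of its full interval with the window; when it qualifies for several
categories the precedence intragenic > promoter_5kb > downstream_5kb >
within_100kb_upstream > within_100kb_downstream > gene_desert applies, which
makes the six fractions exclusive and exhaustive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .intervals import GenomicInterval, GeneModel, nearest_point

logger = logging.getLogger(__name__)

CATEGORIES = (
    "intragenic",
    "promoter_5kb",
    "downstream_5kb",
    "within_100kb_upstream",
    "within_100kb_downstream",
    "gene_desert",
)

PROMOTER_BP = 5_000
NEAR_BP = 100_000


@dataclass(frozen=True)
class LocationCategory:
    label: str
    assigned_gene: str | None

    def __post_init__(self) -> None:
        if self.label not in CATEGORIES:
            raise ValueError(f"unknown category {self.label!r}")
        if (self.label == "gene_desert") != (self.assigned_gene is None):
            raise ValueError("gene_desert iff no assigned gene")


def _windows(gene: GeneModel) -> dict[str, tuple[int, int]]:
    """Strand-aware category windows for one gene (may have start<0, clipped)."""
    s, e = gene.interval.start, gene.interval.end
    if gene.interval.strand == "+":
        return {
            "intragenic": (s, e),
            "promoter_5kb": (s - PROMOTER_BP, s),
            "downstream_5kb": (e, e + PROMOTER_BP),
            "within_100kb_upstream": (s - NEAR_BP, s - PROMOTER_BP),
            "within_100kb_downstream": (e + PROMOTER_BP, e + NEAR_BP),
        }
    return {
        "intragenic": (s, e),
        "promoter_5kb": (e, e + PROMOTER_BP),
        "downstream_5kb": (s - PROMOTER_BP, s),
        "within_100kb_upstream": (e + PROMOTER_BP, e + NEAR_BP),
        "within_100kb_downstream": (s - NEAR_BP, s - PROMOTER_BP),
    }


def _overlaps(peak: GenomicInterval, win: tuple[int, int]) -> bool:
    lo, hi = max(win[0], 0), win[1]
    return min(peak.end, hi) - max(peak.start, lo) >= 1


def categorize_peak(
    peak: GenomicInterval, genes: Sequence[GeneModel]
) -> LocationCategory:
    """Assign a peak its gene-relative category.

    The assigned gene is, among genes qualifying for the winning category,
    the one whose TSS is nearest the peak midpoint (ties toward the smaller
    TSS coordinate).
    """
    near = [
        g
        for g in genes
        if g.chrom == peak.chrom
        and peak.start < g.interval.end + NEAR_BP
        and peak.end > g.interval.start - NEAR_BP
    ]
    if not near:
        return LocationCategory("gene_desert", None)
    mid = peak.midpoint
    for label in CATEGORIES[:-1]:
        qualifying = [g for g in near if _overlaps(peak, _windows(g)[label])]
        if qualifying:
            best = min(qualifying, key=lambda g: (abs(g.tss - mid), g.tss))
            return LocationCategory(label, best.name)
    return LocationCategory("gene_desert", None)


def annotate_peaks(
    peaks: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[LocationCategory]:
    if not genes:
        logger.warning("empty gene list: all peaks assigned gene_desert")
        return [LocationCategory("gene_desert", None) for _ in peaks]
    return [categorize_peak(p, genes) for p in peaks]


@dataclass
class CategoryFractions:
    counts: dict[str, int]
    fractions: dict[str, float]
    within_100kb_fraction: float  # everything except gene_desert
    n_peaks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts[c] for c in CATEGORIES],
                "fraction": [self.fractions[c] for c in CATEGORIES],
            }
        )


def category_fractions(
    peaks: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> CategoryFractions:
    """Fractions of peaks per category (sum to 1) plus the combined
    within-100 kb-of-a-gene fraction."""
    if not peaks:
        raise ValueError("category_fractions requires at least one peak")
    labels = [c.label for c in annotate_peaks(peaks, genes)]
    counts = {c: 0 for c in CATEGORIES}
    for lab in labels:
        counts[lab] += 1
    n = len(peaks)
    fractions = {c: counts[c] / n for c in CATEGORIES}
    return CategoryFractions(counts, fractions, 1.0 - fractions["gene_desert"], n)


@dataclass
class TssProfile:
    """Signed midpoint-to-nearest-TSS distance histogram.

    distance < 0 means the peak midpoint lies upstream of the TSS in the
    gene's orientation; > 0 downstream.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    distances: pd.DataFrame  # peak_id, gene, distance
    n_total: int
    n_within_1kb: int
    n_within_500: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "count": self.counts.astype(int),
            }
        )


def signed_tss_distance(mid: int, gene: GeneModel) -> int:
    """Orientation-aware signed distance from a position to a gene's TSS."""
    raw = mid - gene.tss
    return raw if gene.interval.strand == "+" else -raw


def tss_profile(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 20_000,
    bin: int = 500,
) -> TssProfile:
    """Histogram of signed peak-midpoint distances to the nearest TSS.

    Nearest is by absolute genomic distance (ties toward the smaller TSS
    coordinate).  Peaks beyond +-window are excluded from the histogram but
    counted in ``n_total``; peaks on chromosomes without genes are skipped.
    """
    if window % bin != 0:
        raise ValueError("window must be a multiple of bin")
    tss_by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g))
    rows = []
    for i, p in enumerate(peaks):
        points = tss_by_chrom.get(p.chrom)
        if not points:
            continue
        gene, _ = nearest_point(p.midpoint, points)
        rows.append((i, gene.name, signed_tss_distance(p.midpoint, gene)))
    dist_df = pd.DataFrame(rows, columns=["peak_id", "gene", "distance"])
    d = dist_df["distance"].to_numpy() if len(rows) else np.empty(0, dtype=int)
    edges = np.arange(-window, window + bin, bin)
    inside = d[(d >= -window) & (d <= window)]
    counts, _ = np.histogram(inside, bins=edges)
    return TssProfile(
        bin_edges=edges,
        counts=counts,
        distances=dist_df,
        n_total=len(peaks),
        n_within_1kb=int((np.abs(d) <= 1000).sum()),
        n_within_500=int((np.abs(d) <= 500).sum()),
    )


@dataclass
class ChromosomeDensity:
    table: pd.DataFrame  # chrom, length, count, density
    pearson_r: float | None

    def to_frame(self) -> pd.DataFrame:
        return self.table


def chromosome_density(
    peaks: Sequence[GenomicInterval], chrom_sizes: dict[str, int]
) -> ChromosomeDensity:
    """Per-chromosome peak counts/densities and the count-vs-length Pearson r.

    r is None (undefined) with fewer than 3 chromosomes, or when either
    variable is constant.
    """
    counts = {c: 0 for c in chrom_sizes}
    for p in peaks:
        if p.chrom in counts:
            counts[p.chrom] += 1
    table = pd.DataFrame(
        {
            "chrom": list(chrom_sizes),
            "length": [chrom_sizes[c] for c in chrom_sizes],
            "count": [counts[c] for c in chrom_sizes],
        }
    )
    table["density"] = table["count"] / table["length"]
    r = None
    if len(chrom_sizes) >= 3:
        lengths = table["length"].to_numpy(dtype=float)
        cnt = table["count"].to_numpy(dtype=float)
        if np.ptp(lengths) > 0 and np.ptp(cnt) > 0:
            r = float(sp_stats.pearsonr(lengths, cnt).statistic)
        else:
            # a constant variable carries no linear association
            r = 0.0
    return ChromosomeDensity(table, r)
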