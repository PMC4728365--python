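"""Enrichment statistics: hypergeometric tests, BH FDR, gene-set and
gene-list utilities, and Ward clustering on binary profiles.

The hypergeometric upper tail P(X >= k) is the one statistic every
enrichment question here reduces to — gene sets against an annotation
universe and motif occurrences against genome-wide scan positions alike.
It is evaluated in log space via scipy's hypergeometric survival function;
tests keep an exact rational-arithmetic oracle alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_P = 1e-300  # reported p-values stay in (0, 1]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # selected items annotated
    K: int  # universe items annotated
    n: int  # selection size
    N: int  # universe size
    p: float
    q: float
    significant: bool = False


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n).

    k of n drawn items annotated, K of N universe items annotated.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require K <= N and n <= N")
    if k == 0:
        return 1.0
    p = float(sp_stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, MIN_P), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_set_enrichment(
    selected: set[str],
    universe: set[str],
    annotation: Mapping[str, set[str]],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in a gene
    selection, BH-corrected across the tested terms.

    Terms with no selected gene are not tested (they cannot be enriched and
    would only inflate the correction burden).  Annotation genes outside the
    universe are dropped with a warning.
    """
    if not selected:
        raise ValueError("selected gene set is empty")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected)
    results: list[EnrichmentResult] = []
    dropped = 0
    for term in sorted(annotation):
        genes = annotation[term]
        inside = genes & universe
        dropped += len(genes) - len(inside)
        k = len(inside & selected)
        if k == 0:
            continue
        K = len(inside)
        p = hypergeom_upper_tail(k, K, n, N)
        results.append(EnrichmentResult(term, k, K, n, N, p, q=1.0))
    if dropped:
        logger.warning("dropped %d annotation gene(s) outside the universe", dropped)
    if not results:
        return []
    q = bh_adjust([r.p for r in results])
    results = [
        EnrichmentResult(r.term, r.k, r.K, r.n, r.N, r.p, float(qi), bool(qi < alpha))
        for r, qi in zip(results, q)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term, r.k, r.K, r.n, r.N, r.p, r.q, r.significant)
            for r in results
        ],
        columns=["term", "k", "K", "n", "N", "p", "q", "significant"],
    )


@dataclass
class ListOverlap:
    """Exact Venn partition of up to three named gene lists."""

    regions: dict[frozenset[str], int]
    membership: pd.DataFrame  # gene x list booleans

    def region(self, *names: str) -> int:
        return self.regions.get(frozenset(names), 0)


def gene_list_overlap(lists: Mapping[str, set[str]]) -> ListOverlap:
    """Venn partition counts and a membership table for 2-3 gene lists."""
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    if len(lists) > 3:
        raise ValueError("partition counts are defined for up to three lists")
    names = sorted(lists)
    union = sorted(set().union(*lists.values()))
    membership = pd.DataFrame(
        {name: [g in lists[name] for g in union] for name in names}, index=union
    )
    regions = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(names, r)
    }
    for g in union:
        present = frozenset(name for name in names if g in lists[name])
        regions[present] += 1
    return ListOverlap(regions, membership)


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    merges[i] = (a, b, height, size): clusters a and b (ids < n are leaves,
    >= n earlier merges) joined at the given height into cluster n + i.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]
    leaf_order: list[int]

    def to_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def jaccard_distance_matrix(data: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distance between binary row vectors.

    1 - |a AND b| / |a OR b|; two all-zero vectors are at distance 0.
    """
    x = np.asarray(data, dtype=bool).astype(np.int64)
    inter = x @ x.T
    row = x.sum(axis=1)
    union = row[:, None] + row[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def binary_ward_cluster(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Ward agglomeration of binary profiles under Jaccard distance.

    Distances update by the Lance-Williams Ward formula applied to the
    Jaccard distances (treated as if Euclidean — documented approximation
    for binary attributes).  Ties break on the lexicographically smallest
    cluster-id pair, so the dendrogram is deterministic.
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    data = matrix.to_numpy()
    labels = list(matrix.index if axis == "rows" else matrix.columns)
    if axis == "cols":
        data = data.T
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels on the clustered axis")

    # Lance-Williams on squared distances, reported heights are sqrt —
    # matches the convention of standard ward linkage on a condensed matrix.
    d2: dict[tuple[int, int], float] = {}
    base = jaccard_distance_matrix(data)
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(base[i, j]) ** 2
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    while len(active) > 1:
        best = min(
            (d2[(min(i, j), max(i, j))], i, j)
            for i, j in combinations(sorted(active), 2)
        )
        h2, a, b = best
        na, nb = sizes[a], sizes[b]
        new = next_id
        next_id += 1
        for k in sorted(active - {a, b}):
            nk = sizes[k]
            dak = d2[(min(a, k), max(a, k))]
            dbk = d2[(min(b, k), max(b, k))]
            d2[(k, new)] = (
                (na + nk) * dak + (nb + nk) * dbk - nk * h2
            ) / (na + nb + nk)
        active -= {a, b}
        active.add(new)
        sizes[new] = na + nb
        children[new] = (a, b)
        merges.append((a, b, float(np.sqrt(max(h2, 0.0))), na + nb))

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    return Dendrogram(merges, labels, leaves(next_id - 1))


def write_dendrogram(path, dendrogram: Dendrogram) -> None:
    """Nested-list text serialization plus the leaf order."""
    n = len(dendrogram.labels)

    def render(node: int) -> str:
        if node < n:
            return dendrogram.labels[node]
        a, b, h, _ = dendrogram.merges[node - n]
        return f"({render(a)},{render(b)}):{h:.6g}"

    with open(path, "w") as fh:
        root = n + len(dendrogram.merges) - 1
        fh.write(render(root) + "\n")
        fh.write(
            "leaf_order\t"
            + "\t".join(dendrogram.labels[i] for i in dendrogram.leaf_order)
            + "\n"
        )
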