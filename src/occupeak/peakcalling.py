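"""Three independent, simplified peak callers for single-end ChIP tags.

All three consume a treatment and an input-control tag set and a chromosome
sizes table:

* ``call_peaks_poisson`` — sliding-window Poisson test against a local
  background rate estimated from the control (the local-lambda idea of
  window-based callers; robust to copy-number segments present in both
  lanes).
* ``call_peaks_strand_transition`` — detects the forward-to-reverse strand
  polarity flip that a true occupancy site imprints on single-end tags.
* ``call_peaks_threshold`` — extended-fragment coverage above a fold of the
  genome mean for a minimum run length, with a control-ratio gate; a
  deterministic stand-in for manual track inspection.

Tags are 0-based half-open intervals; a tag's 5' end marks the sonicated
fragment boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, TagAlignment, merge_intervals

logger = logging.getLogger(__name__)

CALLERS = ("poisson", "strand_transition", "threshold")


@dataclass(frozen=True)
class Peak:
    """A called occupancy interval."""

    interval: GenomicInterval
    caller: str
    score: float  # -log10 p (poisson) or fold enrichment (others)
    summit: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak interval")
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclass
class CallerParams:
    """Shared tuning knobs for the three callers.

    fragment_shift : estimated fragment-level shift d between forward and
        reverse 5' pileups; None means "estimate from the data, fall back to
        150 when the strand cross-correlation is weak".
    window : sliding-window width for the poisson caller (bases).
    strand_window : window for strand-transition net counts (bases).
    pvalue_cutoff : Poisson upper-tail significance threshold.
    fold_cutoff : fold enrichment over depth-scaled control (E).
    min_tags : minimum tags around a strand transition (R).
    min_run : minimum run length for the threshold caller (m, bases).
    max_shift : search bound for fragment-shift estimation.
    """

    fragment_shift: int | None = None
    window: int = 300
    strand_window: int = 20
    pvalue_cutoff: float = 1e-5
    fold_cutoff: float = 2.0
    min_tags: int = 10
    min_run: int = 50
    max_shift: int = 1200

    def __post_init__(self) -> None:
        for name in ("window", "strand_window", "min_tags", "min_run", "max_shift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.pvalue_cutoff < 1.0):
            raise ValueError("pvalue_cutoff must be in (0, 1)")
        if self.fold_cutoff <= 0:
            raise ValueError("fold_cutoff must be positive")
        if self.fragment_shift is not None and self.fragment_shift < 0:
            raise ValueError("fragment_shift must be non-negative")


@dataclass(frozen=True)
class ShiftEstimate:
    shift: int
    correlation: float
    low_correlation: bool


def _positions_by_chrom(
    tags: Sequence[TagAlignment],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: sorted arrays of forward / reverse 5' positions."""
    fwd: dict[str, list[int]] = {}
    rev: dict[str, list[int]] = {}
    for t in tags:
        d = fwd if t.interval.strand == "+" else rev
        d.setdefault(t.interval.chrom, []).append(t.five_prime)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in set(fwd) | set(rev):
        out[chrom] = (
            np.sort(np.array(fwd.get(chrom, []), dtype=np.int64)),
            np.sort(np.array(rev.get(chrom, []), dtype=np.int64)),
        )
    return out


def estimate_fragment_shift(
    treatment: Sequence[TagAlignment],
    chrom_sizes: dict[str, int],
    max_shift: int = 1200,
    low_correlation_threshold: float = 0.1,
) -> ShiftEstimate:
    """Strand cross-correlation estimate of the fragment shift d.

    Maximizes the Pearson correlation between the forward 5'-end count
    profile and the reverse profile shifted left by s, over s in
    [0, max_shift].  Cross-products are computed by FFT; means and variances
    use whole-chromosome moments (the shift is tiny relative to chromosome
    length).  Raises on single-strand input; flags a weak optimum
    (correlation < 0.1) so callers can fall back to a conventional default.
    """
    pos = _positions_by_chrom(treatment)
    n_fwd = sum(len(f) for f, _ in pos.values())
    n_rev = sum(len(r) for _, r in pos.values())
    if n_fwd == 0 or n_rev == 0:
        raise ValueError("fragment-shift estimation needs tags on both strands")

    cross = np.zeros(max_shift + 1)
    sum_f = sum_r = sum_f2 = sum_r2 = 0.0
    total_len = 0
    for chrom, (fp, rp) in pos.items():
        L = chrom_sizes[chrom]
        f = np.bincount(fp, minlength=L).astype(np.float64)
        r = np.bincount(rp, minlength=L).astype(np.float64)
        n = 1 << int(np.ceil(np.log2(L + max_shift + 1)))
        # c(s) = sum_x f[x] * r[x + s]
        c = np.fft.irfft(np.conj(np.fft.rfft(f, n)) * np.fft.rfft(r, n), n)
        cross += c[: max_shift + 1]
        sum_f += f.sum()
        sum_r += r.sum()
        sum_f2 += (f * f).sum()
        sum_r2 += (r * r).sum()
        total_len += L
    m = float(total_len)
    mean_f, mean_r = sum_f / m, sum_r / m
    var_f = sum_f2 / m - mean_f**2
    var_r = sum_r2 / m - mean_r**2
    denom = math.sqrt(max(var_f, 0.0) * max(var_r, 0.0))
    if denom == 0:
        corr = np.zeros_like(cross)
    else:
        corr = (cross / m - mean_f * mean_r) / denom
    best = int(np.argmax(corr))
    best_corr = float(corr[best])
    low = best_corr < low_correlation_threshold
    if low:
        logger.warning(
            "fragment-shift cross-correlation is weak (r=%.3f at d=%d)",
            best_corr,
            best,
        )
    return ShiftEstimate(best, best_corr, low)


def resolve_shift(
    treatment: Sequence[TagAlignment],
    chrom_sizes: dict[str, int],
    params: CallerParams,
    fallback: int = 150,
) -> int:
    """Fragment shift from params, or estimated with a conventional fallback."""
    if params.fragment_shift is not None:
        return params.fragment_shift
    try:
        est = estimate_fragment_shift(treatment, chrom_sizes, params.max_shift)
    except ValueError:
        return fallback
    return fallback if est.low_correlation else est.shift


def _shifted_positions(
    pos: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom_sizes: dict[str, int],
    half_shift: int,
) -> dict[str, np.ndarray]:
    """Shift forward tags +d/2, reverse tags -d/2, clip to bounds, sort."""
    out = {}
    for chrom, (fp, rp) in pos.items():
        L = chrom_sizes[chrom]
        shifted = np.concatenate([fp + half_shift, rp - half_shift])
        out[chrom] = np.sort(np.clip(shifted, 0, L - 1))
    return out


def _count_in(sorted_pos: np.ndarray, lo, hi) -> np.ndarray:
    """Counts of sorted positions in [lo, hi) (vectorized over lo/hi)."""
    return np.searchsorted(sorted_pos, hi) - np.searchsorted(sorted_pos, lo)


def _check_sizes(chrom_sizes: dict[str, int]) -> None:
    for chrom, L in chrom_sizes.items():
        if L <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")


def call_peaks_poisson(
    treatment: Sequence[TagAlignment],
    control: Sequence[TagAlignment],
    chrom_sizes: dict[str, int],
    params: CallerParams | None = None,
) -> list[Peak]:
    """Sliding-window Poisson caller with a local control-derived lambda.

    Treatment tags are shifted d/2 toward 3'; windows of width w step w/2.
    A window is significant when the Poisson upper tail of its treatment
    count under lambda_local is below the cutoff, with lambda_local the
    maximum of the genome-wide, 5 kb and 10 kb control rates (centred on the
    window, depth-scaled).  Overlapping significant windows merge into
    peaks; the summit is the maximum of the shifted-tag pileup.
    """
    params = params or CallerParams()
    _check_sizes(chrom_sizes)
    if not treatment:
        return []
    if not control:
        raise ValueError("poisson caller requires a non-empty control")
    d = resolve_shift(treatment, chrom_sizes, params)
    w = params.window
    step = max(w // 2, 1)
    tpos = _shifted_positions(_positions_by_chrom(treatment), chrom_sizes, d // 2)
    cpos_by = _positions_by_chrom(control)
    cpos = {
        c: np.sort(np.concatenate([f, r])) for c, (f, r) in cpos_by.items()
    }
    n_treat = sum(len(p) for p in tpos.values())
    n_ctl = sum(len(p) for p in cpos.values())
    genome_len = sum(chrom_sizes.values())
    ratio = n_treat / n_ctl
    lam_genome = n_ctl * (w / genome_len) * ratio

    peaks: list[Peak] = []
    for chrom in sorted(chrom_sizes):
        t = tpos.get(chrom)
        if t is None or len(t) == 0:
            continue
        L = chrom_sizes[chrom]
        c = cpos.get(chrom, np.empty(0, dtype=np.int64))
        starts = np.arange(0, L, step, dtype=np.int64)
        ends = np.minimum(starts + w, L)
        counts = _count_in(t, starts, ends)
        centers = (starts + ends) // 2
        lam5 = _count_in(c, centers - 2500, centers + 2500) * (w / 5000.0) * ratio
        lam10 = _count_in(c, centers - 5000, centers + 5000) * (w / 10000.0) * ratio
        lam = np.maximum(lam_genome, np.maximum(lam5, lam10))
        with np.errstate(divide="ignore"):
            logp = stats.poisson.logsf(counts - 1, lam)
        sig = logp < math.log(params.pvalue_cutoff)
        if not sig.any():
            continue
        idx = np.flatnonzero(sig)
        neglog10 = -logp[idx] / math.log(10)
        # merge overlapping/adjacent significant windows
        clusters: list[tuple[int, int, float]] = []  # (start, end, score)
        cur_s, cur_e, cur_score = starts[idx[0]], ends[idx[0]], neglog10[0]
        for k in range(1, len(idx)):
            s, e = starts[idx[k]], ends[idx[k]]
            if s <= cur_e:
                cur_e = max(cur_e, e)
                cur_score = max(cur_score, neglog10[k])
            else:
                clusters.append((int(cur_s), int(cur_e), float(cur_score)))
                cur_s, cur_e, cur_score = s, e, neglog10[k]
        clusters.append((int(cur_s), int(cur_e), float(cur_score)))
        for s, e, score in clusters:
            local = t[(t >= s) & (t < e)]
            if len(local):
                cov = np.bincount(local - s, minlength=e - s)
                summit = s + int(np.argmax(cov))
            else:
                summit = (s + e) // 2
            peaks.append(
                Peak(GenomicInterval(chrom, s, e), "poisson", score, summit)
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def call_peaks_strand_transition(
    treatment: Sequence[TagAlignment],
    control: Sequence[TagAlignment],
    chrom_sizes: dict[str, int],
    params: CallerParams | None = None,
) -> list[Peak]:
    """Forward-to-reverse strand polarity transitions as candidate sites.

    Net counts c = forward - reverse are tabulated in non-overlapping
    windows of width ``strand_window``; a candidate site sits at each sign
    transition of c from positive to negative (windows with no tags carry no
    sign).  Candidates keep their site when at least ``min_tags`` treatment
    tags fall within +-w and the fold enrichment over the depth-scaled
    control in the same span is >= ``fold_cutoff``.  Candidates closer than
    2w merge (higher-tag one wins) so peaks, which span [t-w, t+w), never
    overlap.  Score is the control fold enrichment; summit the transition.
    """
    params = params or CallerParams()
    _check_sizes(chrom_sizes)
    if not treatment:
        return []
    w = params.strand_window
    tpos = _positions_by_chrom(treatment)
    cpos_by = _positions_by_chrom(control)
    cpos = {c: np.sort(np.concatenate([f, r])) for c, (f, r) in cpos_by.items()}
    n_treat = len(treatment)
    n_ctl = max(len(control), 1)
    genome_len = sum(chrom_sizes.values())
    ratio = n_treat / n_ctl
    ctl_expected = len(control) * (2 * w + 1) / genome_len

    peaks: list[Peak] = []
    for chrom in sorted(chrom_sizes):
        if chrom not in tpos:
            continue
        fp, rp = tpos[chrom]
        tall = np.sort(np.concatenate([fp, rp]))
        L = chrom_sizes[chrom]
        nwin = (L + w - 1) // w
        f = np.bincount(np.minimum(fp // w, nwin - 1), minlength=nwin)
        r = np.bincount(np.minimum(rp // w, nwin - 1), minlength=nwin)
        net = f.astype(np.int64) - r
        occupied = np.flatnonzero(f + r > 0)
        signs = np.sign(net[occupied])
        nz = signs != 0
        occ, sg = occupied[nz], signs[nz]
        cands: list[tuple[int, int]] = []  # (transition pos, tag count)
        c = cpos.get(chrom, np.empty(0, dtype=np.int64))
        for k in range(1, len(occ)):
            if sg[k - 1] > 0 and sg[k] < 0:
                t = ((occ[k - 1] + 1) * w + occ[k] * w) // 2
                t = min(max(t, 0), L - 1)
                count = int(
                    np.searchsorted(tall, t + w, side="right")
                    - np.searchsorted(tall, t - w)
                )
                if count < params.min_tags:
                    continue
                ctl_count = int(
                    np.searchsorted(c, t + w, side="right")
                    - np.searchsorted(c, t - w)
                )
                scaled_ctl = max(ctl_count, ctl_expected, 1e-9) * ratio
                fold = count / scaled_ctl
                if fold >= params.fold_cutoff:
                    cands.append((t, count))
        # merge candidates closer than 2w, keeping the higher-tag one
        kept: list[tuple[int, int]] = []
        for t, count in cands:
            if kept and t - kept[-1][0] < 2 * w:
                if count > kept[-1][1]:
                    kept[-1] = (t, count)
            else:
                kept.append((t, count))
        for t, count in kept:
            s, e = max(t - w, 0), min(t + w, L)
            ctl_count = int(
                np.searchsorted(c, t + w, side="right") - np.searchsorted(c, t - w)
            )
            scaled_ctl = max(ctl_count, ctl_expected, 1e-9) * ratio
            peaks.append(
                Peak(GenomicInterval(chrom, s, e), "strand_transition",
                     count / scaled_ctl, t)
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def _coverage(
    pos: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom_sizes: dict[str, int],
    frag: int,
) -> dict[str, np.ndarray]:
    """Per-base coverage with tags extended to ``frag`` bases toward 3'."""
    cov = {}
    for chrom, L in chrom_sizes.items():
        diff = np.zeros(L + 1, dtype=np.float64)
        if chrom in pos:
            fp, rp = pos[chrom]
            if len(fp):
                np.add.at(diff, np.clip(fp, 0, L), 1.0)
                np.add.at(diff, np.clip(fp + frag, 0, L), -1.0)
            if len(rp):
                np.add.at(diff, np.clip(rp - frag + 1, 0, L), 1.0)
                np.add.at(diff, np.clip(rp + 1, 0, L), -1.0)
        cov[chrom] = np.cumsum(diff[:-1])
    return cov


def call_peaks_threshold(
    treatment: Sequence[TagAlignment],
    control: Sequence[TagAlignment],
    chrom_sizes: dict[str, int],
    params: CallerParams | None = None,
) -> list[Peak]:
    """Extended-fragment coverage threshold caller.

    Tags are extended to the fragment length (2d) toward 3'; maximal runs of
    at least ``min_run`` bases with coverage >= fold_cutoff x genome-mean
    coverage become peaks, provided the depth-scaled treatment/control
    coverage ratio over the run is also >= fold_cutoff.  Score is the mean
    fold over the genome mean; summit the coverage maximum.
    """
    params = params or CallerParams()
    _check_sizes(chrom_sizes)
    if not treatment:
        return []
    d = resolve_shift(treatment, chrom_sizes, params)
    frag = max(2 * d, 1)
    tcov = _coverage(_positions_by_chrom(treatment), chrom_sizes, frag)
    ccov = _coverage(_positions_by_chrom(control), chrom_sizes, frag)
    genome_len = sum(chrom_sizes.values())
    t_total = sum(float(c.sum()) for c in tcov.values())
    c_total = sum(float(c.sum()) for c in ccov.values())
    if t_total == 0:
        return []
    genome_mean = t_total / genome_len
    ctl_mean = c_total / genome_len if c_total > 0 else 0.0
    depth_ratio = t_total / c_total if c_total > 0 else 1.0

    peaks: list[Peak] = []
    for chrom in sorted(chrom_sizes):
        cov = tcov[chrom]
        mask = cov >= params.fold_cutoff * genome_mean
        if not mask.any():
            continue
        padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
        run_starts = np.flatnonzero(padded == 1)
        run_ends = np.flatnonzero(padded == -1)
        ccv = ccov[chrom]
        for s, e in zip(run_starts, run_ends):
            if e - s < params.min_run:
                continue
            t_sum = float(cov[s:e].sum())
            c_sum = float(ccv[s:e].sum())
            scaled_ctl = max(c_sum, ctl_mean * (e - s), 1e-9) * depth_ratio
            if t_sum / scaled_ctl < params.fold_cutoff:
                continue
            summit = int(s + np.argmax(cov[s:e]))
            score = t_sum / ((e - s) * genome_mean)
            peaks.append(
                Peak(GenomicInterval(chrom, int(s), int(e)), "threshold",
                     score, summit)
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def write_peaks(path, peaks: Sequence[Peak]) -> None:
    """BED6 with name = caller, score = caller score."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.caller}\t{p.score:.6g}\t.\n")


def write_summits(path, peaks: Sequence[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{p.summit}\t{p.summit + 1}\t{p.caller}\t{p.score:.6g}\t.\n"
            )
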