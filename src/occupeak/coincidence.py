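"""Bidirectional overlap fractions between peak sets and feature tracks.

A peak "coincides" with a track when it shares >= 1 bp with any track
interval; each peak counts once however many track intervals it touches,
and conversely for features — the statistics are interval-level fractions,
matching how percent-of-peaks figures are conventionally reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval, Track, merge_intervals, overlap_pairs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoincidenceResult:
    track: str
    n_peaks: int
    n_overlapping: int
    n_features: int
    n_features_overlapping: int
    genome_fraction_track: float

    @property
    def fraction_peaks(self) -> float:
        return self.n_overlapping / self.n_peaks

    @property
    def fraction_features(self) -> float:
        if self.n_features == 0:
            return 0.0
        return self.n_features_overlapping / self.n_features

    @property
    def percent_peaks(self) -> float:
        """Percent of peaks on the track, 2 d.p. (reporting convention)."""
        return round(100.0 * self.fraction_peaks, 2)


def peak_track_coincidence(
    peaks: Sequence[GenomicInterval], track: Track, genome_length: int
) -> CoincidenceResult:
    """Coincidence fractions in both directions plus the track's genome share."""
    if not peaks:
        raise ValueError("peak_track_coincidence requires at least one peak")
    coverage = track.coverage()
    if genome_length < coverage:
        raise ValueError("genome_length smaller than track coverage")
    if not track.intervals:
        logger.warning("track %s is empty; fractions are 0", track.name)
        return CoincidenceResult(track.name, len(peaks), 0, 0, 0, 0.0)
    pairs = overlap_pairs(list(peaks), track.intervals, min_overlap=1)
    peaks_hit = {i for i, _ in pairs}
    feats_hit = {j for _, j in pairs}
    return CoincidenceResult(
        track=track.name,
        n_peaks=len(peaks),
        n_overlapping=len(peaks_hit),
        n_features=len(track.intervals),
        n_features_overlapping=len(feats_hit),
        genome_fraction_track=coverage / genome_length,
    )


@dataclass(frozen=True)
class ConditionComparison:
    track: str
    fold: float | None  # fraction_a / fraction_b; None when undefined
    difference: float


def condition_compare(
    result_a: CoincidenceResult, result_b: CoincidenceResult
) -> ConditionComparison:
    """Fold change and difference of the percent-of-peaks fraction, A vs B."""
    if result_a.track != result_b.track:
        raise ValueError(
            f"track mismatch: {result_a.track!r} vs {result_b.track!r}"
        )
    fa, fb = result_a.fraction_peaks, result_b.fraction_peaks
    fold = None if fb == 0 else fa / fb
    return ConditionComparison(result_a.track, fold, fa - fb)


def enrichment_vs_genome(result: CoincidenceResult) -> float:
    """Ratio of the peak-level fraction to the track's genome fraction.

    > 1 means the feature is over-represented among peaks, < 1
    under-represented.
    """
    if result.genome_fraction_track <= 0:
        raise ValueError("track has zero genome fraction")
    return result.fraction_peaks / result.genome_fraction_track


def coincidence_table(
    results: Sequence[CoincidenceResult], condition: str = ""
) -> pd.DataFrame:
    """Long-format table: condition, track, direction, numerator, denominator,
    fraction."""
    rows = []
    for r in results:
        rows.append(
            (condition, r.track, "peaks_on_track", r.n_overlapping, r.n_peaks,
             r.fraction_peaks)
        )
        rows.append(
            (condition, r.track, "features_on_peaks", r.n_features_overlapping,
             r.n_features, r.fraction_features)
        )
        rows.append(
            (condition, r.track, "track_genome_fraction", 0, 0,
             r.genome_fraction_track)
        )
    return pd.DataFrame(
        rows,
        columns=["condition", "track", "direction", "numerator", "denominator",
                 "fraction"],
    )
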