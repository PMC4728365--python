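"""The three peak callers and the fragment-shift estimator."""

import numpy as np
import pytest

from conftest import recall_precision, truth_sites
from occupeak.intervals import GenomicInterval, TagAlignment, merge_intervals
from occupeak.peakcalling import (
    CallerParams,
    call_peaks_poisson,
    call_peaks_strand_transition,
    call_peaks_threshold,
    estimate_fragment_shift,
)

READ = 36
SIZES = {"chr1": 100_000}


def tag(five_prime, strand, chrom="chr1", sample="treatment"):
    if strand == "+":
        iv = GenomicInterval(chrom, five_prime, five_prime + READ, "+")
    else:
        iv = GenomicInterval(chrom, five_prime - READ + 1, five_prime + 1, "-")
    return TagAlignment(iv, sample)


def paired_pileup(rng, centers, frag_len, n_per_site, jitter=0):
    """Fragments of fixed length shedding one tag per end around each centre."""
    tags = []
    for c in centers:
        for _ in range(n_per_site):
            cc = c + (int(rng.normal(0, jitter)) if jitter else 0)
            tags.append(tag(cc - frag_len // 2, "+"))
            tags.append(tag(cc + frag_len // 2, "-"))
    return tags


class TestFragmentShift:
    def test_recovers_150bp_fragments(self, rng):
        centers = rng.integers(2_000, 98_000, size=600)
        tags = paired_pileup(rng, centers, frag_len=150, n_per_site=1)
        est = estimate_fragment_shift(tags, SIZES, max_shift=400)
        assert 140 <= est.shift <= 160
        assert not est.low_correlation

    def test_coincident_strands_give_zero_shift(self, rng):
        positions = rng.integers(1_000, 99_000, size=1_500)
        tags = [tag(int(p), "+") for p in positions] + [
            tag(int(p), "-") for p in positions
        ]
        est = estimate_fragment_shift(tags, SIZES, max_shift=300)
        assert est.shift == 0

    def test_uniform_tags_flag_low_correlation(self, rng):
        tags = [
            tag(int(p), "+" if s else "-")
            for p, s in zip(
                rng.integers(1_000, 99_000, size=2_000), rng.random(2_000) < 0.5
            )
        ]
        est = estimate_fragment_shift(tags, SIZES, max_shift=300)
        assert est.low_correlation
        assert est.correlation < 0.1

    def test_single_strand_raises(self):
        tags = [tag(1000 + 50 * i, "+") for i in range(100)]
        with pytest.raises(ValueError, match="strand"):
            estimate_fragment_shift(tags, SIZES)


class TestPoissonCaller:
    def params(self):
        return CallerParams(fragment_shift=150)

    def uniform_control(self, rng, n=2_000):
        return [
            tag(int(p), "+" if s else "-", sample="control")
            for p, s in zip(
                rng.integers(500, 99_500, size=n), rng.random(n) < 0.5
            )
        ]

    def test_planted_locus_yields_one_peak(self, rng):
        centers = [50_000] * 250
        treatment = paired_pileup(rng, centers, frag_len=150, n_per_site=1, jitter=50)
        peaks = call_peaks_poisson(
            treatment, self.uniform_control(rng), SIZES, self.params()
        )
        assert len(peaks) == 1
        assert peaks[0].interval.start <= 50_000 < peaks[0].interval.end

    def test_no_enrichment_when_treatment_equals_control(self, rng):
        control = self.uniform_control(rng)
        treatment = [
            TagAlignment(t.interval, "treatment") for t in control
        ]
        peaks = call_peaks_poisson(treatment, control, SIZES, self.params())
        assert peaks == []

    def test_copy_number_gain_in_both_lanes_is_not_a_peak(self, rng):
        # a 10 kb segment at 3x rate in BOTH treatment and control: the
        # local-lambda (5/10 kb control windows) absorbs it
        def lane(sample, base_n):
            tags = [
                tag(int(p), "+" if s else "-", sample=sample)
                for p, s in zip(
                    rng.integers(500, 99_500, size=base_n),
                    rng.random(base_n) < 0.5,
                )
            ]
            extra = base_n // 5  # 2x extra inside 10% of the genome = 3x rate
            tags += [
                tag(int(p), "+" if s else "-", sample=sample)
                for p, s in zip(
                    rng.integers(40_000, 50_000, size=extra),
                    rng.random(extra) < 0.5,
                )
            ]
            return tags

        peaks = call_peaks_poisson(
            lane("treatment", 3_000), lane("control", 3_000), SIZES, self.params()
        )
        assert [
            p for p in peaks if p.interval.start < 50_000 and p.interval.end > 40_000
        ] == []

    def test_empty_treatment_returns_no_peaks(self, rng):
        assert call_peaks_poisson([], self.uniform_control(rng), SIZES) == []

    def test_empty_control_raises(self, rng):
        treatment = self.uniform_control(rng)
        with pytest.raises(ValueError, match="control"):
            call_peaks_poisson(
                [TagAlignment(t.interval, "treatment") for t in treatment],
                [],
                SIZES,
            )

    def test_zero_length_chromosome_raises(self, rng):
        with pytest.raises(ValueError, match="zero-length"):
            call_peaks_poisson(
                [tag(100, "+")], self.uniform_control(rng), {"chr1": 0}
            )


class TestStrandTransitionCaller:
    def params(self):
        return CallerParams(fragment_shift=150)

    def test_bidirectional_pileup_gives_one_peak_at_site(self, rng):
        treatment = paired_pileup(rng, [50_000] * 80, frag_len=30, n_per_site=1)
        peaks = call_peaks_strand_transition(treatment, [], SIZES, self.params())
        assert len(peaks) == 1
        assert abs(peaks[0].summit - 50_000) <= self.params().strand_window

    def test_single_strand_yields_no_transitions(self):
        treatment = [tag(10_000 + 10 * i, "+") for i in range(200)]
        peaks = call_peaks_strand_transition(treatment, [], SIZES)
        assert peaks == []

    def test_two_sites_10kb_apart_give_two_ordered_peaks(self, rng):
        treatment = paired_pileup(
            rng, [40_000] * 80 + [50_000] * 80, frag_len=30, n_per_site=1
        )
        peaks = call_peaks_strand_transition(treatment, [], SIZES, self.params())
        assert len(peaks) == 2
        assert peaks[0].summit < peaks[1].summit
        assert abs(peaks[0].summit - 40_000) <= 2 * self.params().strand_window
        assert abs(peaks[1].summit - 50_000) <= 2 * self.params().strand_window


class TestThresholdCaller:
    def test_flat_coverage_has_no_peaks(self):
        # evenly spaced identical lanes: nothing reaches 2x the genome mean
        treatment = [tag(100 * i + 50, "+") for i in range(999)]
        control = [tag(100 * i + 50, "+", sample="control") for i in range(999)]
        peaks = call_peaks_threshold(
            treatment, control, SIZES, CallerParams(fragment_shift=150)
        )
        assert peaks == []

    def test_stacked_locus_is_called_with_min_run_satisfied(self):
        # 30 identical fragments -> a 300 bp coverage rectangle far above
        # the genome mean
        params = CallerParams(fragment_shift=150, min_run=300)
        treatment = [tag(50_000, "+") for _ in range(30)]
        peaks = call_peaks_threshold(treatment, [], SIZES, params)
        assert len(peaks) == 1
        (peak,) = peaks
        assert peak.interval.start == 50_000
        assert len(peak.interval) == 300

    def test_run_one_base_short_of_min_run_is_dropped(self):
        params = CallerParams(fragment_shift=150, min_run=301)
        treatment = [tag(50_000, "+") for _ in range(30)]
        assert call_peaks_threshold(treatment, [], SIZES, params) == []


class TestCallerInvariants:
    def test_outputs_sorted_disjoint_and_in_bounds(self, strong_data, called_peaksets):
        sizes = strong_data.chrom_sizes
        for name, peaks in called_peaksets.items():
            for p in peaks:
                assert 0 <= p.interval.start < p.interval.end <= sizes[p.interval.chrom]
                assert p.interval.start <= p.summit < p.interval.end
                assert p.score >= 0
            for a, b in zip(peaks, peaks[1:]):
                assert (a.interval.chrom, a.interval.start) <= (
                    b.interval.chrom,
                    b.interval.start,
                )
                if a.interval.chrom == b.interval.chrom:
                    assert a.interval.end <= b.interval.start, name

    def test_relaxing_cutoffs_never_removes_called_bases(self, strong_data):
        d = strong_data

        def coverage(peaks):
            return {
                (iv.chrom, iv.start, iv.end)
                for iv in merge_intervals([p.interval for p in peaks])
            }

        def contains(big, small):
            big_ivs = [GenomicInterval(c, s, e) for c, s, e in big]
            for c, s, e in small:
                if not any(
                    iv.chrom == c and iv.start <= s and iv.end >= e for iv in big_ivs
                ):
                    return False
            return True

        strict = call_peaks_poisson(
            d.treatment, d.control, d.chrom_sizes, CallerParams(pvalue_cutoff=1e-8)
        )
        loose = call_peaks_poisson(
            d.treatment, d.control, d.chrom_sizes, CallerParams(pvalue_cutoff=1e-3)
        )
        assert contains(coverage(loose), coverage(strict))

        strict_t = call_peaks_threshold(
            d.treatment, d.control, d.chrom_sizes, CallerParams(fold_cutoff=3.0)
        )
        loose_t = call_peaks_threshold(
            d.treatment, d.control, d.chrom_sizes, CallerParams(fold_cutoff=1.5)
        )
        assert contains(coverage(loose_t), coverage(strict_t))

    def test_recovery_on_strong_preset(self, strong_data, called_peaksets):
        sites = truth_sites(strong_data)
        for name, peaks in called_peaksets.items():
            recall, precision = recall_precision(peaks, sites)
            assert recall >= 0.9, name
            assert precision >= 0.9, name
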