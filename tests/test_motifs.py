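"""PWM scoring, exact DP p-values, scanning and motif enrichment."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from occupeak.intervals import GenomicInterval, GeneModel
from occupeak.motifs import (
    PWM,
    motif_enrichment,
    motif_enrichment_table,
    motif_tss_distribution,
    peaks_with_motif,
    scan,
    scannable_positions,
    score_pvalue,
    score_window,
)

UNIFORM = np.full(4, 0.25)


def one_hot_pwm(consensus, pseudocount=0.0, background=None):
    m = np.zeros((len(consensus), 4))
    for i, ch in enumerate(consensus):
        m[i, "ACGT".index(ch)] = 1.0
    return PWM("onehot", m, background if background is not None else UNIFORM,
               pseudocount)


def random_pwm(rng, width, name="rnd"):
    return PWM(name, rng.dirichlet(np.ones(4), size=width),
               rng.dirichlet(np.ones(4) * 5))


def enumerate_tail(pwm, threshold_bits):
    """Independent oracle: sum background mass of every word scoring >=
    the threshold (full 4^w enumeration via the integer score grid)."""
    w = pwm.width
    I = pwm.int_matrix
    codes = np.array(list(itertools.product(range(4), repeat=w)))
    scores = I[np.arange(w), codes].sum(axis=1)
    probs = np.prod(pwm.background[codes], axis=1)
    return float(probs[scores >= np.ceil(threshold_bits * 1000 - 1e-9)].sum())


class TestScoreWindow:
    def test_one_hot_consensus_scores_two_bits_per_column(self):
        pwm = one_hot_pwm("ACGTAC")
        assert score_window(pwm, "ACGTAC") == pytest.approx(12.0, abs=1e-2)

    def test_full_mismatch_is_strongly_negative(self):
        pwm = one_hot_pwm("AAAA", pseudocount=1e-4)
        assert score_window(pwm, "TTTT") < -10

    def test_max_scoring_word_is_columnwise_argmax(self, rng):
        pwm = random_pwm(rng, 6)
        I = pwm.int_matrix
        codes = np.array(list(itertools.product(range(4), repeat=6)))
        scores = I[np.arange(6), codes].sum(axis=1)
        best_word = "".join("ACGT"[c] for c in codes[np.argmax(scores)])
        argmax_word = "".join("ACGT"[j] for j in I.argmax(axis=1))
        assert best_word == argmax_word
        assert score_window(pwm, best_word) == pytest.approx(
            scores.max() / 1000, abs=1e-9
        )

    def test_n_gives_minus_infinity(self):
        assert score_window(one_hot_pwm("ACGT"), "ACNT") == float("-inf")

    def test_bad_alphabet_raises(self):
        with pytest.raises(ValueError):
            score_window(one_hot_pwm("ACGT"), "ACXT")

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            score_window(one_hot_pwm("ACGT"), "ACGTA")


class TestScorePvalue:
    def test_minimum_score_has_pvalue_one(self, rng):
        pwm = random_pwm(rng, 5)
        assert score_pvalue(pwm, -1e6) == 1.0

    def test_above_maximum_reports_positive_floor(self, rng):
        pwm = random_pwm(rng, 5)
        I = pwm.int_matrix
        max_bits = I.max(axis=1).sum() / 1000
        p = score_pvalue(pwm, max_bits + 5.0)
        max_mass = float(np.prod(pwm.background[I.argmax(axis=1)]))
        assert 0 < p <= max_mass + 1e-12

    @pytest.mark.parametrize("seed", range(4))
    def test_dp_tail_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, 5)
        for t in rng.uniform(-6, 12, size=20):
            expected = enumerate_tail(pwm, float(t))
            if expected == 0.0:
                continue
            assert score_pvalue(pwm, float(t)) == pytest.approx(
                expected, abs=1e-9
            )


class TestScan:
    def genome_with_plant(self, rng, consensus, pos=5_000, length=20_000):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        return {"chr1": seq[:pos] + consensus + seq[pos + len(consensus):]}

    def test_planted_consensus_is_found_on_plus_strand(self, rng):
        cons = "ACGTCAGTAC"
        genome = self.genome_with_plant(rng, cons)
        pwm = one_hot_pwm(cons, pseudocount=1e-4)
        hits = scan(pwm, genome, pvalue_cutoff=1e-4)
        plus = [h for h in hits if h.interval.strand == "+"]
        assert any(h.interval.start == 5_000 for h in plus)

    def test_palindromic_instance_hits_both_strands(self, rng):
        cons = "ACGCGCGT"  # reverse complement of itself
        genome = self.genome_with_plant(rng, cons)
        pwm = one_hot_pwm(cons, pseudocount=1e-4)
        hits = [h for h in scan(pwm, genome, pvalue_cutoff=1e-3)
                if h.interval.start == 5_000]
        assert {h.interval.strand for h in hits} == {"+", "-"}
        assert len({(h.interval.start, h.interval.end) for h in hits}) == 1

    def test_region_scan_equals_genome_scan_restricted(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=30_000))}
        pwm = random_pwm(rng, 7)
        regions = [
            GenomicInterval("chr1", 2_000, 4_000),
            GenomicInterval("chr1", 10_000, 12_500),
        ]
        region_hits = scan(pwm, genome, regions, pvalue_cutoff=1e-3)
        genome_hits = scan(pwm, genome, pvalue_cutoff=1e-3)
        restricted = [
            h
            for h in genome_hits
            if any(
                h.interval.start >= r.start and h.interval.end <= r.end
                for r in regions
            )
        ]
        assert [
            (h.interval.start, h.interval.strand, h.score) for h in region_hits
        ] == [(h.interval.start, h.interval.strand, h.score) for h in restricted]

    def test_hit_count_invariant_under_genome_reverse_complement(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=15_000))}
        rc = {"chr1": genome["chr1"].translate(comp)[::-1]}
        pwm = random_pwm(rng, 6)
        fwd_hits = scan(pwm, genome, pvalue_cutoff=1e-3)
        rc_hits = scan(pwm, rc, pvalue_cutoff=1e-3)
        assert len(fwd_hits) == len(rc_hits)
        L = 15_000
        mirrored = sorted(
            (L - h.interval.end, "+" if h.interval.strand == "-" else "-")
            for h in rc_hits
        )
        assert mirrored == sorted(
            (h.interval.start, h.interval.strand) for h in fwd_hits
        )

    def test_lowering_cutoff_never_adds_hits(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
        pwm = random_pwm(rng, 6)
        loose = {
            (h.interval.start, h.interval.strand)
            for h in scan(pwm, genome, pvalue_cutoff=1e-2)
        }
        strict = {
            (h.interval.start, h.interval.strand)
            for h in scan(pwm, genome, pvalue_cutoff=1e-4)
        }
        assert strict <= loose

    def test_region_outside_sequence_raises(self, rng):
        genome = {"chr1": "ACGT" * 100}
        with pytest.raises(ValueError, match="outside"):
            scan(random_pwm(rng, 5), genome, [GenomicInterval("chr1", 0, 10_000)])


def exact_upper_tail(k, K, n, N):
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


class TestMotifEnrichment:
    def test_zero_hits_in_peaks_is_certain(self):
        assert motif_enrichment("m", 0, 100, 50, 10_000).p == 1.0

    def test_all_genome_hits_inside_small_peaks(self):
        res = motif_enrichment("m", 8, 40, 8, 2_000)
        assert res.p == pytest.approx(exact_upper_tail(8, 8, 40, 2_000), rel=1e-9)
        assert res.p < 1e-10

    def test_hits_at_expectation_are_not_significant(self):
        # k = n*K/N exactly: 5 = 100*50/1000
        res = motif_enrichment("m", 5, 100, 50, 1_000)
        assert res.p == pytest.approx(exact_upper_tail(5, 50, 100, 1_000), rel=1e-9)
        assert res.p > 0.3

    def test_bh_and_significance_across_motifs(self):
        rs = [
            motif_enrichment("hot", 30, 100, 40, 10_000),
            motif_enrichment("cold", 1, 100, 95, 10_000),
        ]
        out = motif_enrichment_table(rs, alpha=0.05)
        flags = {r.term: r.significant for r in out}
        assert flags == {"hot": True, "cold": False}

    def test_violated_preconditions_raise(self):
        with pytest.raises(ValueError):
            motif_enrichment("m", 10, 5, 50, 100)


class TestMotifTssDistribution:
    GENES = [GeneModel(GenomicInterval("chr1", 10_000, 15_000, "+"), "g1")]

    def hit(self, start, width=6):
        return type(
            "H", (), {"interval": GenomicInterval("chr1", start, start + width, "+")}
        )()

    def test_no_motif_bearing_peaks_gives_empty_histogram(self):
        peaks = [GenomicInterval("chr1", 0, 200)]
        prof = motif_tss_distribution(peaks, [], self.GENES)
        assert prof.n_total == 0
        assert prof.counts.sum() == 0

    def test_all_bearing_peaks_at_tss_fall_in_central_bin(self):
        peaks = [GenomicInterval("chr1", 9_900, 10_100)]
        prof = motif_tss_distribution(peaks, [self.hit(9_950)], self.GENES)
        assert prof.n_total == 1
        assert prof.n_within_500 == 1

    def test_planted_distances_reproduce_histogram(self):
        # peaks with midpoints at TSS+250 and TSS+5250; hits inside both
        peaks = [
            GenomicInterval("chr1", 10_150, 10_350),
            GenomicInterval("chr1", 15_150, 15_350),
            GenomicInterval("chr1", 30_000, 30_200),  # no hit inside
        ]
        hits = [self.hit(10_200), self.hit(15_200)]
        prof = motif_tss_distribution(peaks, hits, self.GENES, window=20_000,
                                      bin=500)
        assert prof.n_total == 2
        assert prof.counts.sum() == 2
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        occupied = centers[prof.counts > 0]
        assert len(occupied) == 2

    def test_peaks_with_motif_requires_full_containment(self):
        peaks = [GenomicInterval("chr1", 100, 200)]
        inside = [self.hit(150)]
        straddling = [self.hit(197)]
        assert peaks_with_motif(peaks, inside) == peaks
        assert peaks_with_motif(peaks, straddling) == []


def test_scannable_positions_counts_both_strands():
    assert scannable_positions([100, 50], 10) == 2 * (91 + 41)
    assert scannable_positions([5], 10) == 0
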