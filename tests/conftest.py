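import numpy as np
import pytest

from occupeak.consensus import cluster_peaks
from occupeak.peakcalling import (
    CallerParams,
    call_peaks_poisson,
    call_peaks_strand_transition,
    call_peaks_threshold,
)
from occupeak.simulate import preset, simulate_dataset


@pytest.fixture(scope="session")
def strong_data():
    """The 'strong' recovery conditions: dense sites, sparse background."""
    return simulate_dataset(preset("strong", seed=1))


@pytest.fixture(scope="session")
def called_peaksets(strong_data):
    d = strong_data
    params = CallerParams()
    return {
        "poisson": call_peaks_poisson(d.treatment, d.control, d.chrom_sizes, params),
        "strand_transition": call_peaks_strand_transition(
            d.treatment, d.control, d.chrom_sizes, params
        ),
        "threshold": call_peaks_threshold(d.treatment, d.control, d.chrom_sizes, params),
    }


@pytest.fixture(scope="session")
def consensus_clusters(called_peaksets):
    return cluster_peaks(list(called_peaksets.values()))


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)


def truth_sites(data):
    return [(r.chrom, int(r.pos)) for r in data.truth.sites.itertuples()]


def recall_precision(peaks, sites, half_width=500):
    """Match = >=1 bp overlap between a peak and [site-half, site+half)."""
    def hits_site(p, c, pos):
        return (
            p.chrom == c and p.start < pos + half_width and p.end > pos - half_width
        )

    intervals = [getattr(p, "interval", p) for p in peaks]
    recall = sum(
        any(hits_site(iv, c, pos) for iv in intervals) for c, pos in sites
    ) / len(sites)
    precision = (
        sum(any(hits_site(iv, c, pos) for c, pos in sites) for iv in intervals)
        / len(intervals)
        if intervals
        else 0.0
    )
    return recall, precision
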