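import numpy as np
import pandas as pd
import pytest

from checflow.annotations import GenomeAnnotation, Transcript, define_promoters
from checflow.tracks import SignalTrack
from checflow import synthetic as syn


@pytest.fixture(scope="session")
def small_world():
    """Default synthetic world shared by read-only tests (seed 7)."""
    annotation, genome, truth = syn.simulate_genome(seed=7)
    return annotation, genome, truth


@pytest.fixture(scope="session")
def small_promoters(small_world):
    annotation, _, _ = small_world
    return define_promoters(annotation)


@pytest.fixture
def toy_annotation():
    """Two genes on one 50 kb chromosome, both strands, no neighbors nearby."""
    return GenomeAnnotation(
        {"chrI": 50_000},
        [
            Transcript("plusG", "chrI", "+", 10_000, 10_900, 10_000, 11_000),
            Transcript("minusG", "chrI", "-", 30_999, 30_100, 30_000, 31_000),
        ],
    )


@pytest.fixture
def uniform_track():
    def make(length=50_000, value=1.0, chrom="chrI", total=None):
        t = SignalTrack({chrom: np.full(length, float(value))})
        if total is not None:
            t.declared_total = float(total)
        return t

    return make
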