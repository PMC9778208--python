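import numpy as np
import pytest

from oriquant.genome import BinnedTrack, GenomeBuild


@pytest.fixture
def small_genome() -> GenomeBuild:
    # second chromosome length not a bin multiple: exercises the tail bin
    return GenomeBuild(("chrA", "chrB"), (10_000, 7_430))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220)


def random_track(
    genome: GenomeBuild, rng: np.random.Generator, bin_width: int = 50
) -> BinnedTrack:
    t = BinnedTrack.zeros(genome, bin_width)
    for chrom in t.values:
        t.values[chrom] = rng.gamma(2.0, 2.0, size=len(t.values[chrom]))
    return t
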