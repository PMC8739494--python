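import numpy as np
import pytest

from uvsuscept.genome import BinnedTrack, GenomeLayout


@pytest.fixture
def layout() -> GenomeLayout:
    """Two small chromosomes with explicit centromeres."""
    return GenomeLayout(
        chromosomes=[("chr1", 10_000_000), ("chr2", 8_000_000)],
        centromeres={"chr1": (4_800_000, 5_000_000), "chr2": (3_500_000, 3_700_000)},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_track(layout: GenomeLayout, bin_size: int, values_fn) -> BinnedTrack:
    """Build a track whose values come from values_fn(chrom, n_bins)."""
    track = BinnedTrack.zeros(layout, bin_size)
    for chrom in track.values:
        track.values[chrom] = np.asarray(
            values_fn(chrom, len(track.values[chrom])), dtype=float
        )
    return track
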