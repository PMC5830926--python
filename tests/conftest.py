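import numpy as np
import pytest

from netterm.signal import FragmentRecord, SignalTrack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_fragments(rng, chrom_size=10_000, n=500, chrom="chr1"):
    """Random small fragment library for oracle comparisons."""
    starts = rng.integers(0, chrom_size - 120, size=n)
    lengths = rng.integers(1, 120, size=n)
    strands = rng.choice(["+", "-"], size=n)
    return [
        FragmentRecord(chrom, int(s), int(min(s + l, chrom_size)), str(st),
                       mapq=int(rng.integers(0, 61)), name=f"f{i}")
        for i, (s, l, st) in enumerate(zip(starts, lengths, strands))
    ]


def uniform_track(chrom_sizes, value, mode="three_prime_end", library_size=None):
    """Track with a constant value at every base on both strands."""
    total = sum(chrom_sizes.values()) * 2 * value
    track = SignalTrack(chrom_sizes, mode,
                        library_size=int(total) if library_size is None else library_size)
    for key in track.data:
        track.data[key][:] = value
    return track


@pytest.fixture
def fragment_factory():
    return random_fragments


@pytest.fixture
def uniform_track_factory():
    return uniform_track
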