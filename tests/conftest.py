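import numpy as np
import pytest

from radpe.radbin import RadBin, RadTag
from radpe.seqio import ReadPair, SequenceRead
from radpe.simulate import generate_genome


def make_pair(r1: str, r2: str, sample: str = "S1", rid: str = "r", q: int = 40) -> ReadPair:
    return ReadPair(
        read1=SequenceRead(f"{rid}/1", r1, tuple([q] * len(r1))),
        read2=SequenceRead(f"{rid}/2", r2, tuple([q] * len(r2))),
        sample=sample,
    )


def make_tiling_bin(
    region: str,
    depth: float = 20,
    read_len: int = 80,
    rng: np.random.Generator | None = None,
    sample: str = "S1",
    tag_length: int = 39,
) -> RadBin:
    """A bin whose read-2 sequences uniformly tile ``region``."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n_pairs = max(1, int(depth * len(region) / read_len))
    pairs = []
    for i in range(n_pairs):
        s = int(rng.integers(0, len(region) - read_len + 1))
        pairs.append(
            make_pair(region[:60], region[s : s + read_len], sample=sample, rid=f"r{i}")
        )
    return RadBin(
        tag=RadTag(region[:tag_length], n_pairs),
        pairs=pairs,
        region_length_estimate=len(region),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(4000, seed=101)
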