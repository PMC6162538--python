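import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paleocomp.fcm_core import reverse_complement
from paleocomp.seqio import ReadRecord, SequenceRecord

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def sample_reads(
    genome: str,
    n: int,
    rng: np.random.Generator,
    read_length: int = 101,
    both_strands: bool = True,
) -> list[ReadRecord]:
    """Error-free reads drawn uniformly from a genome (both strands)."""
    reads = []
    for i in range(n):
        start = int(rng.integers(0, len(genome) - read_length + 1))
        seq = genome[start : start + read_length]
        if both_strands and rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(ReadRecord(id=f"read{i}", sequence=seq, quality="I" * read_length))
    return reads


def coverage_reads(
    genome: str, coverage: float, rng: np.random.Generator, read_length: int = 101
) -> list[ReadRecord]:
    n = int(round(coverage * len(genome) / read_length))
    return sample_reads(genome, n, rng, read_length)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng) -> SequenceRecord:
    return SequenceRecord(id="g1", sequence=random_dna(rng, 5000))
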