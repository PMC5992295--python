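from __future__ import annotations

import numpy as np
import pytest

from viropair.homology import revcomp
from viropair.read_qc import Read

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def tiled_reads(
    genome: str,
    rng: np.random.Generator,
    n_reads: int,
    read_len: int = 150,
    label: str = "s",
    prefix: str = "r",
) -> list[Read]:
    """Error-free reads at uniform random starts and strands."""
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, len(genome) - read_len + 1))
        frag = genome[start : start + read_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append(Read(f"{prefix}_{i:05d}", frag, "I" * read_len, source=label))
    return reads


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def session_rng() -> np.random.Generator:
    return np.random.default_rng(7)
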