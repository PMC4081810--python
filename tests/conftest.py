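import numpy as np
import pytest

from popdiv.seqio import Alignment, SampleMeta


@pytest.fixture
def toy_alignment() -> Alignment:
    """Four samples, two populations, three haplotypes."""
    return Alignment(
        "toy",
        ("a1", "a2", "b1", "b2"),
        ("AAAA", "AAAA", "AAAT", "AATT"),
    )


@pytest.fixture
def toy_meta() -> list[SampleMeta]:
    return [
        SampleMeta("a1", "north"),
        SampleMeta("a2", "north"),
        SampleMeta("b1", "south"),
        SampleMeta("b2", "south"),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140703)


def make_alignment(seqs: list[str], prefix: str = "s") -> Alignment:
    ids = tuple(f"{prefix}{i + 1}" for i in range(len(seqs)))
    return Alignment("fix", ids, tuple(seqs))
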