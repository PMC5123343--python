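from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hmmens.io_formats import Alignment, FamilyDatabase, Sequence
from hmmens.synthetic import SimParams, make_benchmark

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def balanced_newick(n: int, prefix: str = "s") -> str:
    """A complete balanced binary tree over n = 2^k leaves, unit branches."""
    labels = [f"{prefix}{i + 1:03d}" for i in range(n)]

    def rec(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return labels[lo]
        mid = (lo + hi) // 2
        return f"({rec(lo, mid)}:1,{rec(mid, hi)}:1)"

    return rec(0, n) + ";"


def block_alignment(
    n: int, length: int, seed: int = 0, n_blocks: int = 1, block_noise: float = 0.05,
    prefix: str = "s",
) -> Alignment:
    """n rows in ``n_blocks`` equal blocks; rows within a block are near
    copies of the block consensus (per-site substitution prob
    ``block_noise``), so within-block identity is high and between-block
    identity is at background level."""
    rng = np.random.default_rng(seed)
    from hmmens.io_formats import AMINO_ACIDS

    rows = []
    per_block = n // n_blocks
    for b in range(n_blocks):
        consensus = rng.integers(0, 20, size=length)
        for i in range(per_block):
            codes = consensus.copy()
            flip = rng.random(length) < block_noise
            codes[flip] = rng.integers(0, 20, size=int(flip.sum()))
            rows.append(
                Sequence(
                    f"{prefix}{b * per_block + i + 1:03d}",
                    "".join(AMINO_ACIDS[c] for c in codes),
                )
            )
    return Alignment(rows)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A small, easy (high-identity) benchmark shared across tests."""
    return make_benchmark(
        SimParams(
            seed=7,
            n_families=5,
            family_size=(14, 14),
            root_length=(40, 50),
        )
    )


@pytest.fixture(scope="session")
def tiny_database(tiny_benchmark) -> FamilyDatabase:
    return tiny_benchmark.database
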