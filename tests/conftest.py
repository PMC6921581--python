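"""Shared fixtures: a compact synthetic study reused across module tests.

The small study trades depth for speed (unit tests check logic, not power);
the acceptance tests build their own full-size study.
"""
from __future__ import annotations

import numpy as np
import pytest

from plastkit.quant import ReadAlignmentSet
from plastkit.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, depth=60.0)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def make_read_set(
    reads: list[tuple[int, str, str]],
    reference_length: int = 50,
    flag: int = 83,
    quals: list[str] | None = None,
    individual: str = "toy",
) -> ReadAlignmentSet:
    """Hand-built alignments: (pos, cigar, seq) triples, all one flag."""
    n = len(reads)
    return ReadAlignmentSet(
        individual=individual,
        reference_id="ref",
        reference_length=reference_length,
        qname=[f"r{i}" for i in range(n)],
        flag=np.full(n, flag, dtype=np.int64),
        pos=np.array([r[0] for r in reads], dtype=np.int64),
        cigar=[r[1] for r in reads],
        seq=[r[2] for r in reads],
        qual=quals,
    )
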