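"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def all_feasible_pairs(M: int) -> list[tuple[int, int]]:
    """Every feasible (copy count, homozygote count) pair for a population
    of size M: 0 <= kp <= 2M with max(0, kp - M) <= cP <= kp // 2."""
    return [
        (kp, cP)
        for kp in range(2 * M + 1)
        for cP in range(max(0, kp - M), kp // 2 + 1)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240121)
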