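"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ampccs.io import Reference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ref(rng):
    from ampccs.simulate import random_reference

    return random_reference(200, rng, name="amp200")


def brute_force_semiglobal_score(read: str, ref: str, match=2, mismatch=-4,
                                 gap_open=-6, gap_extend=-1) -> int:
    """Exhaustive affine-gap fitting-alignment score, written plainly.

    Independent of the vectorized implementation: three explicit matrices,
    no prefix-scan trick. Gap of length k costs gap_open + (k-1)*gap_extend;
    reference overhang at either end is free, the read is fully consumed.
    """
    n, m = len(read), len(ref)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference (I)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (D)
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            if j == 0:
                H[i][j] = E[i][j]
                continue
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if read[i - 1] == ref[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return max(H[n])


def count_switches(pattern) -> int:
    """Independent switch-count oracle: adjacent differing parent labels."""
    informative = [p for p in pattern if p is not None]
    return sum(1 for a, b in zip(informative, informative[1:]) if a != b)


def make_reference(sequence: str, name: str = "ref") -> Reference:
    return Reference(name=name, sequence=sequence)
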