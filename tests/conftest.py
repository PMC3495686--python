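"""Shared fixtures and independent alignment oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from teclassifier import build_index, default_spec, generate_genome


def smith_waterman(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -3.0,
):
    """Plain affine-gap Smith-Waterman, written independently of the package's
    alignment machinery; returns (identity_pct, matches, aln_len, score) of
    the best local alignment.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open + gap_extend, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open + gap_extend, F[i - 1, j] + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    # traceback from the best cell
    i, j = bi, bj
    matches = aln_len = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
            aln_len += 1
            i, j = i - 1, j - 1
        elif H[i, j] == E[i, j]:
            while j > 0 and E[i, j] != H[i, j - 1] + gap_open + gap_extend:
                aln_len += 1
                j -= 1
            aln_len += 1
            j -= 1
        else:
            while i > 0 and F[i, j] != H[i - 1, j] + gap_open + gap_extend:
                aln_len += 1
                i -= 1
            aln_len += 1
            i -= 1
    identity = 100.0 * matches / aln_len if aln_len else 0.0
    return identity, matches, aln_len, best


def brute_force_te_free_max(intervals: list[tuple[int, int]], length: int) -> int:
    """Longest uncovered run via an explicit per-position covered scan."""
    covered = np.zeros(length, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    best = run = 0
    for c in covered:
        run = 0 if c else run + 1
        best = max(best, run)
    return best


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def fixture_genome():
    """The standard synthetic study conditions: 3 x 100 kb chromosomes, one
    100-nt TE planted 25 times at 95% identity, ten unique hairpins."""
    return generate_genome(default_spec(seed=0))


@pytest.fixture(scope="session")
def fixture_index(fixture_genome):
    return build_index(fixture_genome.records, k=11)
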