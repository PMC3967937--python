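"""Shared oracles and helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from blockcoal import SiteFrequencySpectrum


def genotype_matrix_for_sfs(sfs: SiteFrequencySpectrum) -> np.ndarray:
    """An arbitrary genotype matrix (sites x individuals) realizing an
    integer-count SFS; any assignment of carriers realizes the same SFS."""
    n = sfs.n
    rows = []
    for i, count in zip(sfs.freqs, sfs.xi):
        count = int(round(count))
        assert count == sfs.xi[i - 1], "oracle needs integer counts"
        for _ in range(count):
            row = np.zeros(n, dtype=int)
            row[:i] = 1
            rows.append(row)
    return np.array(rows) if rows else np.zeros((0, n), dtype=int)


def brute_force_pi(sfs: SiteFrequencySpectrum) -> float:
    """Mean pairwise difference over all sample pairs, by enumeration."""
    G = genotype_matrix_for_sfs(sfs)
    n = sfs.n
    diffs = [
        np.sum(G[:, a] != G[:, b]) for a, b in itertools.combinations(range(n), 2)
    ]
    return float(np.mean(diffs))


def independent_tajimas_d(xi: np.ndarray) -> float:
    """Direct transcription of the 1989 formulas, kept independent of the
    package implementation."""
    xi = np.asarray(xi, dtype=float)
    n = len(xi) + 1
    i = np.arange(1, n)
    S = xi.sum()
    pi = np.sum(xi * i * (n - i)) / (n * (n - 1) / 2.0)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return (pi - S / a1) / np.sqrt(c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140327)
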