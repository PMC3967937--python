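"""Site-frequency-spectrum container and summary statistics.

The site frequency spectrum (SFS) of a sample of ``n`` haploid individuals
is the vector ``xi[i]`` (``i = 1..n-1``) counting derived mutations carried
by exactly ``i`` sampled individuals.  It is the universal currency of this
package: the structured-coalescent predictions, the Bolthausen-Sznitman
limit, and the forward-time simulator all produce one, and every summary
statistic used to diagnose interference selection (pairwise diversity,
Tajima's D, mean minor allele frequency, the high-frequency "U-shape"
statistic) is computed from it.

Entries may be observed integer counts or real-valued expectations; the
statistics accept both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteFrequencySpectrum",
    "SummaryStats",
    "UndefinedStatisticError",
    "pairwise_diversity",
    "tajimas_d",
    "mean_minor_allele_freq",
    "ushape_statistic",
    "normalize_sfs",
    "neutral_sfs_expectation",
    "summary_stats",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given spectrum
    (e.g. Tajima's D with no segregating sites)."""


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """An (observed or expected) site frequency spectrum.

    Parameters
    ----------
    n : int
        Sample size (number of haploid individuals), ``n >= 2``.
    xi : ndarray of shape (n-1,)
        ``xi[i-1]`` is the number (or expected number) of derived mutations
        present in exactly ``i`` of the ``n`` sampled individuals.  Entries
        must be non-negative.
    """

    n: int
    xi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = int(self.n)
        if n < 2:
            raise ValueError(f"sample size must be >= 2, got {n}")
        xi = np.asarray(self.xi, dtype=float)
        if xi.ndim != 1 or xi.shape[0] != n - 1:
            raise ValueError(
                f"xi must have length n-1 = {n - 1}, got shape {xi.shape}"
            )
        if np.any(xi < 0):
            raise ValueError("SFS entries must be non-negative")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "xi", xi)

    @property
    def segregating_sites(self) -> float:
        """Total (expected) number of segregating sites, S = sum xi_i."""
        return float(self.xi.sum())

    @property
    def freqs(self) -> np.ndarray:
        """Derived-allele count classes i = 1..n-1."""
        return np.arange(1, self.n)

    def scaled(self, c: float) -> "SiteFrequencySpectrum":
        """Return a copy with all entries multiplied by ``c >= 0``."""
        return SiteFrequencySpectrum(self.n, self.xi * c)


@dataclass(frozen=True)
class SummaryStats:
    """The bundle of SFS summaries used throughout the package."""

    pi: float
    tajimas_d: float
    mean_maf: float
    ushape: float
    segregating_sites: float


def pairwise_diversity(sfs: SiteFrequencySpectrum) -> float:
    r"""Average number of pairwise differences.

    .. math:: \pi = \sum_i \xi_i \, \frac{2 i (n - i)}{n (n - 1)}

    which equals the mean number of differences over all ``n(n-1)/2``
    sample pairs.  For the neutral expectation ``xi_i = theta / i`` this
    returns ``theta``.
    """
    n = sfs.n
    i = sfs.freqs
    return float(np.sum(sfs.xi * i * (n - i)) * 2.0 / (n * (n - 1)))


def _tajima_constants(n: int) -> tuple[float, float, float]:
    """Tajima (1989) normalization constants a1 and (e1, e2)."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2

def tajimas_d(sfs: SiteFrequencySpectrum) -> float:
    """Tajima's D computed from the spectrum.

    ``D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))`` with the standard
    sample-variance constants.  Applied to an *expected* SFS this treats
    ``S = sum xi_i`` as if it were an observed count, which is the usual
    plug-in approximation.  Exactly zero for the neutral shape
    ``xi_i = theta/i``.
    """
    S = sfs.segregating_sites
    if S <= 0:
        raise UndefinedStatisticError("Tajima's D undefined with S = 0")
    a1, e1, e2 = _tajima_constants(sfs.n)
    num = pairwise_diversity(sfs) - S / a1
    var = e1 * S + e2 * S * max(S - 1.0, 0.0)
    if var <= 0:
        # single (fractional) segregating site: variance degenerate
        raise UndefinedStatisticError("Tajima's D variance normalizer <= 0")
    return float(num / math.sqrt(var))


def mean_minor_allele_freq(sfs: SiteFrequencySpectrum) -> float:
    """Average minor allele frequency, weighted by the spectrum.

    Returns ``sum_i xi_i * min(i, n-i)/n / sum_i xi_i``; lies in
    ``[1/n, 1/2]`` and is invariant under rescaling of the SFS.  A deficit
    relative to the neutral value signals an excess of rare alleles.
    """
    S = sfs.segregating_sites
    if S <= 0:
        raise UndefinedStatisticError("mean MAF undefined for an empty SFS")
    i = sfs.freqs
    maf = np.minimum(i, sfs.n - i) / sfs.n
    return float(np.sum(sfs.xi * maf) / S)


def ushape_statistic(sfs: SiteFrequencySpectrum) -> float:
    """Non-monotonicity of the spectrum at high derived-allele frequency.

    Defined as the ratio of the top bin to a mid-frequency reference bin,
    normalized by its value under the neutral shape ``xi_i ∝ 1/i``:

    ``ushape = [xi_{n-1} / xi_m] / [m / (n-1)]``, with ``m = ceil((n-1)/2)``.

    Equals 1 for the exact neutral spectrum; values above 1 indicate the
    high-frequency uptick ("U-shape") diagnostic of genealogical imbalance
    and multiple mergers.
    """
    n = sfs.n
    if n < 4:
        raise UndefinedStatisticError("ushape requires n >= 4")
    m = math.ceil((n - 1) / 2)
    ref = sfs.xi[m - 1]
    if ref <= 0:
        raise UndefinedStatisticError("ushape reference bin is zero")
    return float((sfs.xi[n - 2] / ref) / (m / (n - 1)))


def normalize_sfs(sfs: SiteFrequencySpectrum, mode: str = "by_singletons") -> np.ndarray:
    """Scale-free spectrum shape.

    ``by_singletons`` divides by ``xi_1`` (first entry becomes exactly 1);
    ``by_pi`` divides by the pairwise diversity.  Either way the output is
    invariant under ``xi -> c*xi``.
    """
    if mode == "by_singletons":
        norm = sfs.xi[0]
    elif mode == "by_pi":
        norm = pairwise_diversity(sfs)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if norm <= 0:
        raise UndefinedStatisticError(f"normalizer for mode {mode!r} is zero")
    return sfs.xi / norm


def neutral_sfs_expectation(n: int, theta: float) -> SiteFrequencySpectrum:
    """Expected neutral spectrum ``E[xi_i] = theta / i`` (infinite sites,
    constant population size)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    i = np.arange(1, int(n))
    return SiteFrequencySpectrum(int(n), theta / i)


def summary_stats(sfs: SiteFrequencySpectrum) -> SummaryStats:
    """Compute the full statistic bundle in one pass."""
    return SummaryStats(
        pi=pairwise_diversity(sfs),
        tajimas_d=tajimas_d(sfs),
        mean_maf=mean_minor_allele_freq(sfs),
        ushape=ushape_statistic(sfs),
        segregating_sites=sfs.segregating_sites,
    )
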