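"""The infinitesimal (fitness-variance) limit.

When selected mutations are individually weak but collectively common
(``Ns -> 0``, ``NU -> infinity``), silent-site diversity ceases to depend on
the individual fitness effects and is controlled by a single parameter: the
population-scaled standard deviation in fitness, ``Nsigma``.  This module
provides

* :class:`DFE` — discrete distributions of fitness effects and the
  root-mean-square mapping onto an equivalent single-effect model;
* :func:`nsigma_map` — the traveling-wave prediction of ``Nsigma`` as a
  function of the scaled parameters, via the control parameter
  ``zeta = (Ns)^2 (NU) = N^3 U <s^2>``;
* :func:`deterministic_variance` — the independent-sites (mutation-selection
  balance) variance benchmark ``sigma^2 = U s``;
* :func:`bolthausen_sznitman_expected_sfs` — Monte-Carlo expected SFS shape
  in the ``Nsigma -> infinity`` limit, where the genealogy converges to the
  Bolthausen-Sznitman multiple-merger coalescent.

The ``Nsigma`` map is a self-consistency relation: fitness variance
accumulates neutrally (at rate ``U <s^2>`` per generation) over the pairwise
coalescence timescale ``T2``, while ``T2`` itself shortens as fitness
variance builds up, crossing over from the neutral value ``N`` to the
multiple-merger timescale ``~ ln(Nsigma)/sigma``.  In scaled units
``x = Nsigma`` this closes to

    zeta = x^2 * (1 + c * x^3 / ((1 + x)^2 * ln(1 + x)))

which is strictly increasing in ``x``, obeys ``x^2 -> zeta`` as
``zeta -> 0``, and gives ``x ~ (zeta * ln x / c)^{1/5}``-type sublinear
growth deep in the interference regime — far below both the deterministic
benchmark and the neutral-accumulation value.  The single order-one
constant ``c`` is fixed once against the reference interference parameter
set ``Ns = 30, NU = 300`` (the *Drosophila* dot-chromosome regime, where
``Nsigma ~ 90``) and frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .sfs import SiteFrequencySpectrum

__all__ = [
    "DFE",
    "InfinitesimalState",
    "rms_effective_s",
    "nsigma_map",
    "nsigma_from_zeta",
    "zeta_from_nsigma",
    "deterministic_variance",
    "bolthausen_sznitman_expected_sfs",
    "C_INTERFERENCE",
]

#: Order-one constant of the coalescence-rate crossover in the Nsigma map,
#: calibrated once against the dot-chromosome reference point (see module
#: docstring) and frozen.
C_INTERFERENCE = 1.65678


@dataclass(frozen=True)
class DFE:
    """A discrete distribution of fitness effects.

    ``atoms`` is a sequence of ``(s_j, U_j)`` pairs: effect ``s_j`` (positive
    for deleterious mutations by convention; beneficial atoms carry ``s < 0``
    and are accepted for the rms map and the forward simulator) occurring at
    genome-wide rate ``U_j`` per generation.  Continuous DFEs enter only via
    user-side discretization into atoms.
    """

    atoms: tuple[tuple[float, float], ...]

    def __init__(self, atoms: Sequence[tuple[float, float]]):
        atoms = tuple((float(s), float(u)) for s, u in atoms)
        for s, u in atoms:
            if u < 0:
                raise ValueError("mutation rates must be non-negative")
        object.__setattr__(self, "atoms", atoms)

    @classmethod
    def single(cls, s: float, U: float) -> "DFE":
        return cls([(s, U)])

    @property
    def total_U(self) -> float:
        return sum(u for _, u in self.atoms)

    @property
    def mean_sq(self) -> float:
        """Mutation-rate-weighted mean squared effect ``<s^2>``."""
        U = self.total_U
        if U == 0:
            return 0.0
        return sum(u * s * s for s, u in self.atoms) / U

    @property
    def mean_effect(self) -> float:
        """Mutation-rate-weighted mean (signed, deleterious ``s > 0``)."""
        U = self.total_U
        if U == 0:
            return 0.0
        return sum(u * s for s, u in self.atoms) / U


def rms_effective_s(dfe: DFE) -> float:
    """Root-mean-square effect ``s_eff = <s^2>^{1/2}``.

    In the infinitesimal limit a population with DFE ``rho(s)`` is
    equivalent to one where every mutation has effect ``s_eff`` at the same
    total rate, because the fitness variance input ``U <s^2>`` is the only
    property of the DFE that survives the limit.
    """
    if dfe.total_U <= 0:
        raise ValueError("rms effect undefined for an empty DFE (total_U = 0)")
    return math.sqrt(dfe.mean_sq)


@dataclass(frozen=True)
class InfinitesimalState:
    """Result of the Nsigma map at one parameter combination."""

    zeta: float         # control parameter (Ns)^2 (NU)
    nsigma: float       # N times the fitness standard deviation
    sigma_sq_det: float  # deterministic benchmark U*s (0 if N not given)


def zeta_from_nsigma(x: float) -> float:
    """Closed-form inverse of the Nsigma map: ``zeta`` producing ``Nsigma = x``."""
    if x < 0:
        raise ValueError("Nsigma must be >= 0")
    if x == 0:
        return 0.0
    return x * x * (1.0 + C_INTERFERENCE * x**3 / ((1.0 + x) ** 2 * math.log1p(x)))


def nsigma_from_zeta(zeta: float) -> float:
    """Solve the crossover relation for ``Nsigma`` given ``zeta >= 0``."""
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    if zeta == 0:
        return 0.0
    # bracket in log-x: zeta(x) is strictly increasing
    lo, hi = math.sqrt(zeta) * 1e-3, math.sqrt(zeta) * 1.001
    # zeta(x) >= x^2, so x <= sqrt(zeta); shrink lo until it brackets
    while zeta_from_nsigma(lo) > zeta:
        lo *= 1e-2
        if lo < 1e-300:
            raise ArithmeticError("Nsigma bracket collapsed")
    return brentq(lambda x: zeta_from_nsigma(x) - zeta, lo, hi,
                  xtol=1e-300, rtol=1e-12)


def nsigma_map(Ns: float, NU: float, N: int | None = None) -> InfinitesimalState:
    """Traveling-wave prediction of the scaled fitness standard deviation.

    Parameters are population-scaled: ``Ns = N s``, ``NU = N U``.  ``N`` is
    only needed to report the deterministic variance benchmark in
    per-generation units; the map itself depends on the parameters only
    through ``zeta = (Ns)^2 (NU)``.
    """
    if not (math.isfinite(Ns) and math.isfinite(NU)):
        raise ValueError("Ns and NU must be finite")
    if Ns < 0 or NU < 0:
        raise ValueError("Ns and NU must be >= 0")
    zeta = Ns * Ns * NU
    x = nsigma_from_zeta(zeta)
    sigma_sq_det = (NU / N) * (Ns / N) if N else float("nan")
    return InfinitesimalState(zeta=zeta, nsigma=x, sigma_sq_det=sigma_sq_det)


def deterministic_variance(U: float, s: float) -> float:
    """Independent-sites fitness variance at mutation-selection balance.

    With Poisson(``lambda = U/s``) mutation counts and additive effect ``s``,
    ``sigma_det^2 = lambda s^2 = U s``.  Interference makes the realized
    variance much smaller than this benchmark.
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    if U < 0:
        raise ValueError("U must be >= 0")
    return U * s


def bolthausen_sznitman_expected_sfs(
    n: int, reps: int = 2000, seed: int = 0
) -> SiteFrequencySpectrum:
    """Monte-Carlo expected SFS shape under the Bolthausen-Sznitman coalescent.

    Merger rates for a given set of ``k`` of ``b`` lineages are
    ``lambda_{b,k} = (k-2)! (b-k)! / (b-1)!``.  Branch lengths are recorded
    with the expected-waiting-time substitution (time to next event replaced
    by its expectation), and the output is normalized by the singleton bin —
    the shape is what matters here, since in the large-``Nsigma`` limit it is
    independent of all underlying parameters.
    """
    n = int(n)
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    # rate of *some* k-merger out of b lineages: C(b,k) * (k-2)!(b-k)!/(b-1)!
    #   = b! / (k! (b-k)!) * (k-2)!(b-k)!/(b-1)! = b / (k (k-1))
    xi = np.zeros(n - 1)
    for _ in range(reps):
        leaves = np.ones(n, dtype=np.int64)
        active = list(range(n))
        while len(active) > 1:
            b = len(active)
            ks = np.arange(2, b + 1)
            rates = b / (ks * (ks - 1.0))
            total = rates.sum()
            dt = 1.0 / total
            for i in active:
                c = leaves[i]
                if c < n:
                    xi[c - 1] += dt
            k = int(rng.choice(ks, p=rates / total))
            merged = rng.choice(len(active), size=k, replace=False)
            merged_idx = [active[j] for j in merged]
            keep = merged_idx[0]
            for i in merged_idx[1:]:
                leaves[keep] += leaves[i]
            drop = set(merged_idx[1:])
            active = [i for i in active if i not in drop]
    xi /= reps
    if n > 2:
        xi = xi / xi[0]
    else:
        xi = np.array([1.0])
    return SiteFrequencySpectrum(n, xi)
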