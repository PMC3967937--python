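"""Background selection: Poisson fitness classes and the structured coalescent.

In the background selection *limit* (rare interference) the fraction of
individuals carrying ``k`` deleterious mutations follows a Poisson
distribution with mean ``lambda = U/s``, and the genealogy of a neutral
locus is a structured coalescent: lineages "migrate" down through the
fitness classes (tracing their deleterious mutations backward in time) and
coalesce only when they occupy the same class, at a rate inversely
proportional to the class size ``N h_k``.

This module provides the closed-form diversity reductions (first-order
``e^{-lambda}``, the higher-order correction used to define the
interference/background boundary, and the recombining single-site formula),
a Monte-Carlo backward-time structured coalescent for one or more effect
classes (numba-accelerated, with the expected-waiting-time substitution),
and the regime classifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import exp1
from scipy.stats import poisson

from .infinitesimal import DFE
from .sfs import SiteFrequencySpectrum, pairwise_diversity

__all__ = [
    "PopulationParams",
    "FitnessClassDistribution",
    "CoalescentResult",
    "poisson_class_weights",
    "bsl_reduction_first_order",
    "bsl_reduction_corrected",
    "bsl_reduction_asymptotic",
    "structured_pair_t2",
    "bsl_reduction_recombining",
    "structured_coalescent_expected_sfs",
    "classify_regime",
    "EULER_GAMMA",
]

logger = logging.getLogger(__name__)

EULER_GAMMA = 0.5772156649015329

_DEFAULT_TAIL_TOL = 1e-8


@dataclass(frozen=True)
class PopulationParams:
    """Population-scaled model parameters.

    ``N`` haploid individuals; deleterious mutations from ``dfe`` across the
    genome; total crossover map length ``R`` per genome per generation;
    neutral mutation rate ``U_neutral`` at the focal locus.
    """

    N: int
    dfe: DFE
    R: float = 0.0
    U_neutral: float = 0.0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.R < 0 or self.U_neutral < 0:
            raise ValueError("rates must be >= 0")

    @property
    def NU(self) -> float:
        return self.N * self.dfe.total_U

    @property
    def NR(self) -> float:
        return self.N * self.R

    @property
    def Ns(self) -> float:
        (s, _), = self.dfe.atoms  # single-effect only
        return self.N * s

    @property
    def lam(self) -> float:
        """Deleterious load lambda = U/s (single-effect DFEs with s > 0)."""
        (s, u), = self.dfe.atoms
        if s <= 0:
            raise ValueError("lambda defined only for deleterious s > 0")
        return u / s


@dataclass(frozen=True)
class FitnessClassDistribution:
    """Truncated Poisson(lambda) class weights h_k, k = 0..k_max."""

    lam: float
    weights: np.ndarray
    k_max: int


def poisson_class_weights(
    lam: float, tail_tol: float = _DEFAULT_TAIL_TOL
) -> FitnessClassDistribution:
    """Poisson fitness-class weights ``h_k = e^{-lam} lam^k / k!`` truncated
    so that the omitted tail mass is below ``tail_tol``."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return FitnessClassDistribution(0.0, np.array([1.0]), 0)
    k_max = int(poisson.isf(tail_tol, lam))
    while poisson.sf(k_max, lam) >= tail_tol:
        k_max += 1
    weights = poisson.pmf(np.arange(k_max + 1), lam)
    return FitnessClassDistribution(float(lam), weights, k_max)


def bsl_reduction_first_order(lam: float) -> float:
    """First-order background-selection reduction ``pi/pi0 = e^{-lambda}``:
    diversity scales with the size of the mutation-free class."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return math.exp(-lam)


def _delay_integral(lam: float) -> float:
    """A(lambda) = E[H_K] for K ~ Poisson(lambda), H_k the harmonic number.

    Equal to ``int_0^lam (1 - e^{-t})/t dt = gamma + ln(lam) + E1(lam)``.
    This is the scaled expected time for a lineage to descend from its
    sampled fitness class to the mutation-free class (in units of 1/s).
    """
    if lam <= 0:
        return 0.0
    if lam < 1e-4:
        return lam - lam * lam / 4.0
    return EULER_GAMMA + math.log(lam) + float(exp1(lam))


def bsl_reduction_asymptotic(Ns: float, NU: float) -> float:
    """Closed-form strong-selection approximation to the corrected reduction.

    Decomposing the pairwise coalescence time into a mutational descent
    ("delay") phase plus coalescence in the mutation-free class gives

        pi/pi0 ~ e^{-lambda} + (2/Ns) * A(lambda),
        A(lambda) = gamma + ln(lambda) + E1(lambda),

    with ``lambda = NU/Ns``.  Used for fast brackets and sanity checks; the
    quantitative prediction is :func:`bsl_reduction_corrected`.  Clamped
    at 1 (the additive decomposition overshoots outside its validity range).
    """
    if Ns <= 0:
        raise ValueError("Ns must be > 0")
    if NU < 0:
        raise ValueError("NU must be >= 0")
    if NU == 0:
        return 1.0
    lam = NU / Ns
    return min(math.exp(-lam) + (2.0 / Ns) * _delay_integral(lam), 1.0)


_MAX_LAMBDA = 2000.0


def structured_pair_t2(
    Ns: float, NU: float, tail_tol: float = _DEFAULT_TAIL_TOL
) -> float:
    """Exact expected pairwise coalescence time (units of ``N``) under the
    single-effect fitness-class coalescent.

    The two sampled lineages start in classes ``k1, k2`` drawn from the
    (truncated) Poisson weights; a lineage in class ``k`` steps down at
    scaled rate ``k Ns`` and a pair sharing class ``k`` coalesces at scaled
    rate ``1/h_k``.  Expected absorption times follow the backward
    recursion

        T(k1,k2) = [1 + k1 Ns T(k1-1,k2) + k2 Ns T(k1,k2-1)] / rho,
        rho = (k1+k2) Ns + 1{k1=k2}/h_{k1},

    solved along anti-diagonals.  This is the quantity Monte-Carlo runs of
    the structured coalescent estimate, computed here without noise.
    """
    if Ns <= 0:
        raise ValueError("Ns must be > 0")
    if NU < 0:
        raise ValueError("NU must be >= 0")
    if NU == 0:
        return 1.0
    lam = NU / Ns
    if lam > _MAX_LAMBDA:
        raise ArithmeticError(
            f"deleterious load lambda={lam:.3g} too extreme to evaluate"
        )
    dist = poisson_class_weights(lam, tail_tol)
    h = dist.weights
    kmax = dist.k_max
    start = h.copy()
    start[kmax] += max(1.0 - h.sum(), 0.0)  # clamped tail mass
    T = np.zeros((kmax + 1, kmax + 1))
    T[0, 0] = h[0]
    for d in range(1, 2 * kmax + 1):
        k1 = np.arange(max(0, d - kmax), min(d, kmax) + 1)
        k2 = d - k1
        rho = d * Ns + np.where(k1 == k2, 1.0 / h[k1], 0.0)
        val = np.ones_like(rho)
        nz1 = k1 > 0
        val[nz1] += k1[nz1] * Ns * T[k1[nz1] - 1, k2[nz1]]
        nz2 = k2 > 0
        val[nz2] += k2[nz2] * Ns * T[k1[nz2], k2[nz2] - 1]
        T[k1, k2] = val / rho
    return float(start @ T @ start)


def bsl_reduction_corrected(Ns: float, NU: float) -> float:
    """Corrected background-selection reduction in pairwise diversity.

    ``pi/pi0 = T2/N`` with ``T2`` the exact two-lineage structured
    coalescent absorption time (:func:`structured_pair_t2`): the
    first-order ``e^{-lambda}`` plus all descent-phase and off-class-0
    coalescence corrections.  Reduces to ``e^{-lambda}`` as
    ``Ns -> infinity`` at fixed ``lambda``; as a function of ``Ns`` at
    fixed ``Nsigma`` (or fixed ``NU``) it attains the interior minimum
    that defines the critical line.  Accurate provided ``Ns`` is not too
    small (near and beyond the critical line the fitness-class assumption
    itself breaks down — which is exactly what the coarse-graining map is
    for).
    """
    val = structured_pair_t2(Ns, NU)
    if not math.isfinite(val):
        raise ArithmeticError(
            f"corrected reduction non-finite at Ns={Ns}, NU={NU}"
        )
    return min(val, 1.0)


def bsl_reduction_recombining(U: float, s: float, R: float) -> float:
    """Single-site background-selection reduction with recombination.

    For a neutral site at the center of a chromosome with uniformly
    distributed deleterious sites (total rate ``U``, effect ``s``, total map
    length ``R``), integrating the classic per-site factor
    ``exp[-u s/(s+r)^2]`` over map positions gives

        pi/pi0 = exp[-U / (s + R/2)].

    Reduces to ``e^{-U/s}`` at ``R = 0`` and tends to 1 as ``R``grows;
    monotone non-decreasing in ``R``.
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    if U < 0 or R < 0:
        raise ValueError("U and R must be >= 0")
    return math.exp(-U / (s + R / 2.0))


# ---------------------------------------------------------------------------
# Structured coalescent Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoalescentResult:
    """Output of a structured-coalescent Monte-Carlo run.

    ``expected_sfs`` holds mean branch lengths (generations) subtending each
    descendant count — multiply by a per-generation neutral mutation rate to
    get expected mutation counts.  ``t2`` is the mean pairwise coalescence
    time in generations (``pi/pi0 = t2/N``).
    """

    expected_sfs: SiteFrequencySpectrum
    t2: float
    n: int
    reps: int
    mc_se_pi: float
    warnings: tuple[str, ...] = ()


@njit(cache=False)
def _sc_kernel(n, s_arr, lam_arr, hmat, kmax_arr, N, reps, seed0):  # pragma: no cover
    """Backward-time fitness-class coalescent for J effect classes.

    Lineage state: vector k = (k_1..k_J).  Migration k_j -> k_j - 1 at rate
    k_j s_j; pairs in identical class vectors coalesce at rate
    1/(N prod_j h_{k_j}).  Waiting times replaced by their expectation;
    events chosen proportionally to rate.  Returns (mean SFS branch lengths,
    sum of per-rep T2, sum of squared T2, clamped-sample count).
    """
    J = s_arr.shape[0]
    dims = kmax_arr + 1
    strides = np.ones(J, np.int64)
    for j in range(1, J):
        strides[j] = strides[j - 1] * dims[j - 1]
    nkeys = strides[J - 1] * dims[J - 1]
    # stationary probability of each class vector (product of Poisson pmfs)
    hkey = np.ones(nkeys, np.float64)
    for key in range(nkeys):
        rem = key
        p = 1.0
        for j in range(J):
            kj = rem % dims[j]
            rem //= dims[j]
            p *= hmat[j, kj]
        hkey[key] = p

    xi_sum = np.zeros(n - 1, np.float64)
    t2_sum = 0.0
    t2_sqsum = 0.0
    n_clamped = 0

    K = np.empty((n, J), np.int64)
    key = np.empty(n, np.int64)
    leaves = np.empty(n, np.int64)
    mig = np.empty(n, np.float64)
    alive = np.empty(n, np.uint8)
    count = np.zeros(nkeys, np.int64)
    occ = np.empty(n, np.int64)       # occupied keys (with duplicates pruned)
    xi_rep = np.empty(n - 1, np.float64)

    for rep in range(reps):
        np.random.seed((seed0 + 7919 * rep) % 2147483629)
        count[:] = 0
        for i in range(n):
            kk = 0
            m = 0.0
            for j in range(J):
                kij = np.random.poisson(lam_arr[j])
                if kij > kmax_arr[j]:
                    kij = kmax_arr[j]
                    n_clamped += 1
                K[i, j] = kij
                kk += kij * strides[j]
                m += kij * s_arr[j]
            key[i] = kk
            mig[i] = m
            leaves[i] = 1
            alive[i] = 1
            count[kk] += 1
        m_act = n
        xi_rep[:] = 0.0

        while m_act > 1:
            # --- total rates -------------------------------------------------
            tot_mig = 0.0
            n_occ = 0
            for i in range(n):
                if alive[i]:
                    tot_mig += mig[i]
                    k = key[i]
                    seen = False
                    for q in range(n_occ):
                        if occ[q] == k:
                            seen = True
                            break
                    if not seen:
                        occ[n_occ] = k
                        n_occ += 1
            tot_coal = 0.0
            for q in range(n_occ):
                c = count[occ[q]]
                if c > 1:
                    tot_coal += c * (c - 1) * 0.5 / (N * hkey[occ[q]])
            total = tot_mig + tot_coal
            dt = 1.0 / total
            for i in range(n):
                if alive[i] and leaves[i] < n:
                    xi_rep[leaves[i] - 1] += dt

            u = np.random.random() * total
            if u < tot_mig or tot_coal == 0.0:
                # migration: pick lineage, then effect class
                acc = 0.0
                tgt = -1
                for i in range(n):
                    if alive[i]:
                        acc += mig[i]
                        if acc >= u:
                            tgt = i
                            break
                if tgt < 0:
                    for i in range(n - 1, -1, -1):
                        if alive[i]:
                            tgt = i
                            break
                u2 = np.random.random() * mig[tgt]
                acc = 0.0
                jj = J - 1
                for j in range(J):
                    acc += K[tgt, j] * s_arr[j]
                    if acc >= u2:
                        jj = j
                        break
                count[key[tgt]] -= 1
                K[tgt, jj] -= 1
                key[tgt] -= strides[jj]
                mig[tgt] -= s_arr[jj]
                count[key[tgt]] += 1
            else:
                # coalescence: pick class, then a uniform pair within it
                v = u - tot_mig
                acc = 0.0
                ck = np.int64(-1)
                for q in range(n_occ):
                    c = count[occ[q]]
                    if c > 1:
                        acc += c * (c - 1) * 0.5 / (N * hkey[occ[q]])
                        ck = occ[q]
                        if acc >= v:
                            break
                c = count[ck]
                a = np.random.randint(c)
                b = np.random.randint(c - 1)
                if b >= a:
                    b += 1
                i1 = -1
                i2 = -1
                idx = 0
                for i in range(n):
                    if alive[i] and key[i] == ck:
                        if idx == a:
                            i1 = i
                        if idx == b:
                            i2 = i
                        idx += 1
                leaves[i1] += leaves[i2]
                alive[i2] = 0
                count[ck] -= 1
                m_act -= 1

        # pairwise coalescence time from this replicate's branch lengths
        t2 = 0.0
        for i in range(1, n):
            t2 += xi_rep[i - 1] * i * (n - i)
        t2 /= n * (n - 1.0)
        t2_sum += t2
        t2_sqsum += t2 * t2
        for i in range(n - 1):
            xi_sum[i] += xi_rep[i]

    return xi_sum / reps, t2_sum, t2_sqsum, n_clamped


def structured_coalescent_expected_sfs(
    effects: Sequence[tuple[float, float]] | DFE,
    N: int,
    n: int,
    reps: int = 10_000,
    seed: int = 0,
    tail_tol: float = _DEFAULT_TAIL_TOL,
) -> CoalescentResult:
    """Monte-Carlo expected SFS and pairwise coalescence time under the
    (multi-class) structured coalescent.

    Parameters
    ----------
    effects : sequence of (s_j, U_j) pairs or DFE
        Deleterious effect classes (per-generation units, ``s_j > 0``).
        Atoms with ``U_j = 0`` are dropped.
    N : int
        Haploid population size (sets the within-class coalescence rate
        ``1/(N h_k)`` and the time unit of the output).
    n : int
        Sample size.
    reps : int
        Monte-Carlo replicates; each uses a deterministic stream derived
        from ``(seed, replicate)``.
    """
    if isinstance(effects, DFE):
        atoms = effects.atoms
    else:
        atoms = tuple((float(s), float(u)) for s, u in effects)
    atoms = tuple((s, u) for s, u in atoms if u > 0)
    for s, u in atoms:
        if s <= 0:
            raise ValueError("structured coalescent requires deleterious s > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not atoms:
        atoms = ((1.0, 0.0),)  # pure Kingman: one empty class

    J = len(atoms)
    s_arr = np.array([s for s, _ in atoms], dtype=float)
    lam_arr = np.array([u / s for s, u in atoms], dtype=float)
    dists = [poisson_class_weights(lam, tail_tol) for lam in lam_arr]
    kmax_arr = np.array([d.k_max for d in dists], dtype=np.int64)
    width = int(kmax_arr.max()) + 1
    hmat = np.zeros((J, width), dtype=float)
    for j, d in enumerate(dists):
        hmat[j, : d.k_max + 1] = d.weights

    seed0 = (int(seed) % 2147483629) or 1
    xi, t2_sum, t2_sqsum, n_clamped = _sc_kernel(
        int(n), s_arr, lam_arr, hmat, kmax_arr, float(N), int(reps), seed0
    )
    t2 = t2_sum / reps
    var = max(t2_sqsum / reps - t2 * t2, 0.0)
    se_t2 = math.sqrt(var / reps)
    warnings: list[str] = []
    if n_clamped:
        msg = f"{n_clamped} sampled lineage classes clamped to k_max"
        logger.warning(msg)
        warnings.append(msg)
    if se_t2 > 0.05 * max(t2, 1e-300):
        msg = f"Monte-Carlo s.e. of T2 is {se_t2 / t2:.1%} of T2; increase reps"
        logger.warning(msg)
        warnings.append(msg)
    return CoalescentResult(
        expected_sfs=SiteFrequencySpectrum(n, xi),
        t2=float(t2),
        n=int(n),
        reps=int(reps),
        mc_se_pi=2.0 * se_t2,  # pi = 2 u T2, reported in branch-length units
        warnings=tuple(warnings),
    )


def coalescent_pi_ratio(result: CoalescentResult, N: int) -> float:
    """Reduction in pairwise diversity implied by a coalescent run:
    ``pi/pi0 = T2/N`` (with T2 recovered from the expected SFS)."""
    sfs = result.expected_sfs
    return pairwise_diversity(sfs) / (2.0 * N)


def classify_regime(
    Ns: float,
    NU: float,
    mode: str = "critical_line",
    observed_pi_ratio: float | None = None,
) -> str:
    """Classify a parameter combination as ``"background"`` or
    ``"interference"``.

    ``critical_line`` mode places the point relative to the critical line
    (the locus of maximal diversity reduction of the corrected formula at
    fixed ``Nsigma``): weak-selection side -> interference.
    ``prediction_error`` mode flags interference when the observed
    ``pi/pi0`` deviates from the corrected prediction by more than 50%.
    """
    if mode == "prediction_error":
        if observed_pi_ratio is None:
            raise ValueError("prediction_error mode needs observed_pi_ratio")
        pred = bsl_reduction_corrected(Ns, NU)
        return (
            "interference"
            if abs(observed_pi_ratio / pred - 1.0) > 0.5
            else "background"
        )
    if mode != "critical_line":
        raise ValueError(f"unknown mode {mode!r}")
    from .coarsegrain import critical_ns_for_zeta  # local import: no cycle

    if NU <= 0:
        return "background"
    ns_star = critical_ns_for_zeta(Ns * Ns * NU)
    return "interference" if Ns < ns_star * (1.0 - 1e-9) else "background"
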