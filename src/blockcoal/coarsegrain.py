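"""The coarse-graining map: critical line and diversity predictions.

The central algorithm of the package.  A population deep in the
interference regime (many weak selected polymorphisms) is replaced by an
*equivalent* population on the boundary of the background-selection regime
with the same scaled fitness standard deviation ``Nsigma`` — fewer,
stronger mutations creating the same variance in fitness — where the
structured coalescent is accurate:

1. compute ``Nsigma`` from ``(Ns, NU)`` via the infinitesimal-limit map;
2. find the point on the *critical line* with that ``Nsigma``;
3. evaluate the structured coalescent (and the corrected analytic
   reduction) at the mapped point.

The critical line is the locus of maximal diversity reduction of the
corrected background-selection formula at fixed ``Nsigma``: for each
``Nsigma`` the corrected ``pi/pi0`` has an interior minimum as a function
of ``Ns`` along the constraint ``Nsigma(Ns, NU) = const``, and the
structured coalescent starts to break down near that minimum (close to
where Muller's ratchet begins to click frequently).  Populations on the
weak-selection side of the line are "interference"; the rest are
"background", where the structured coalescent applies directly and the map
is the identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Any

import numpy as np

from .bgs import (
    bsl_reduction_corrected,
    bsl_reduction_first_order,
    classify_regime,
    structured_coalescent_expected_sfs,
    EULER_GAMMA,
    _delay_integral,
)
from .infinitesimal import nsigma_from_zeta, zeta_from_nsigma
from .sfs import SiteFrequencySpectrum

__all__ = [
    "CriticalLinePoint",
    "CoarseGrainedPrediction",
    "critical_ns_for_zeta",
    "stationarity_residual",
    "critical_line_point",
    "coarse_grain_params",
    "coarse_grained_pi_ratio",
    "predict_asexual",
    "predict_two_effect",
]

logger = logging.getLogger(__name__)

_RESIDUAL_TOL = 1e-6


@dataclass(frozen=True)
class CriticalLinePoint:
    """A point on the interference/background boundary."""

    ns_star: float
    nu_star: float
    nsigma: float

    @property
    def zeta(self) -> float:
        return self.ns_star**2 * self.nu_star

    @property
    def lam(self) -> float:
        return self.nu_star / self.ns_star


@dataclass(frozen=True)
class CoarseGrainedPrediction:
    """A coarse-grained diversity prediction.

    ``mapped`` equals ``original`` (as a point) in the background regime.
    ``pi_ratio`` comes from the corrected analytic formula at the mapped
    point; ``expected_sfs``/``t2`` from the structured-coalescent run when
    one was requested (``None`` for parameters-only calls).
    """

    original: tuple[float, float]          # (Ns, NU)
    mapped: CriticalLinePoint
    regime: str
    pi_ratio: float
    expected_sfs: SiteFrequencySpectrum | None = None
    t2: float | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)


def _stationarity_asymptotic(Ns: float, zeta: float) -> float:
    """Residual of the closed-form (strong-selection) stationarity condition
    at fixed ``zeta`` — used only to seed the exact solver.

    Setting d/dNs of ``e^{-lam} + (2/Ns) A(lam)`` to zero along
    ``lam = zeta/Ns^3`` gives

        h(Ns) = 3 lam e^{-lam} Ns - 2 A(lam) - 6 (1 - e^{-lam}).
    """
    lam = zeta / Ns**3
    e = math.exp(-lam)
    A = _delay_integral(lam)
    return 3.0 * lam * e * Ns - 2.0 * A - 6.0 * (1.0 - e)


def _asymptotic_ns_guess(zeta: float) -> float:
    lo = 1.0
    hi = max(20.0 * zeta ** (1.0 / 3.0), 50.0)
    while _stationarity_asymptotic(lo, zeta) > 0 and lo > 1e-6:
        lo *= 0.5
    grid = np.geomspace(lo, hi, 128)
    h_prev = _stationarity_asymptotic(grid[0], zeta)
    for x0, x1 in zip(grid[:-1], grid[1:]):
        h = _stationarity_asymptotic(x1, zeta)
        if h_prev < 0 <= h:
            return math.sqrt(x0 * x1)
        h_prev = h
    return 8.0 / 3.0


def stationarity_residual(Ns: float, zeta: float, h: float = 1e-4) -> float:
    """Relative stationarity residual ``d ln(pi/pi0) / d ln Ns`` of the
    corrected reduction along the constraint ``(Ns)^2 NU = zeta``
    (central differences in ``ln Ns``)."""
    from .bgs import structured_pair_t2

    u = math.log(Ns)
    f = lambda uu: structured_pair_t2(math.exp(uu), zeta * math.exp(-2.0 * uu))
    return (math.log(f(u + h)) - math.log(f(u - h))) / (2.0 * h)


@lru_cache(maxsize=4096)
def critical_ns_for_zeta(zeta: float, tol: float = 1e-8) -> float:
    """Boundary selection strength ``Ns*`` for control parameter ``zeta``.

    Minimizes the corrected reduction over ``Ns`` at fixed ``zeta`` by
    root-finding the (log-log) stationarity residual with a safeguarded
    secant/bisection iteration, seeded by the closed-form asymptotic
    stationarity condition.  As ``zeta -> 0`` the solution tends to the
    asymptotic value ``Ns* = 8/3``.
    """
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    if zeta == 0:
        return 8.0 / 3.0
    u0 = math.log(_asymptotic_ns_guess(zeta))
    # bracket the sign change of the residual around the seed
    step = 0.25
    a = b = None
    ga = gb = 0.0
    for j in range(12):
        lo_u, hi_u = u0 - step * (j + 1), u0 + step * (j + 1)
        g_lo = stationarity_residual(math.exp(lo_u), zeta)
        g_hi = stationarity_residual(math.exp(hi_u), zeta)
        if g_lo < 0 < g_hi:
            a, b, ga, gb = lo_u, hi_u, g_lo, g_hi
            break
    if a is None:
        raise ArithmeticError(f"no stationarity sign change near zeta={zeta}")
    side = 0
    for _ in range(300):
        # Illinois false position: halve the retained endpoint's weight so
        # neither end stagnates
        u = (a * gb - b * ga) / (gb - ga) if gb != ga else 0.5 * (a + b)
        if not (a < u < b):
            u = 0.5 * (a + b)
        g = stationarity_residual(math.exp(u), zeta)
        if abs(g) < tol or (b - a) < 1e-13:
            return math.exp(u)
        if g < 0:
            a, ga = u, g
            if side == -1:
                gb *= 0.5
            side = -1
        else:
            b, gb = u, g
            if side == 1:
                ga *= 0.5
            side = 1
    best_u = a if abs(ga) < abs(gb) else b
    g = stationarity_residual(math.exp(best_u), zeta)
    if abs(g) > _RESIDUAL_TOL:
        raise ArithmeticError(
            f"critical-line solver stalled at zeta={zeta}: residual {g:.2e}"
        )
    return math.exp(best_u)


def critical_line_point(nsigma: float) -> CriticalLinePoint:
    """The boundary point ``(Ns*, NU*)`` sharing the given ``Nsigma``."""
    if nsigma <= 0:
        raise ValueError("nsigma must be > 0")
    zeta = zeta_from_nsigma(nsigma)
    ns = critical_ns_for_zeta(zeta)
    nu = zeta / ns**2
    return CriticalLinePoint(ns_star=ns, nu_star=nu, nsigma=nsigma)


def coarse_grain_params(Ns: float, NU: float) -> CoarseGrainedPrediction:
    """Map ``(Ns, NU)`` to its coarse-grained equivalent (no coalescent run).

    Interference-regime inputs map to the critical-line point with the same
    ``Nsigma``; background-regime inputs map to themselves.  ``pi_ratio``
    is the corrected analytic reduction evaluated at the mapped point.
    """
    if not (math.isfinite(Ns) and math.isfinite(NU)) or NU < 0:
        raise ValueError("Ns, NU must be finite with NU >= 0")
    zeta = Ns * Ns * NU
    nsigma = nsigma_from_zeta(zeta)
    regime = classify_regime(Ns, NU, mode="critical_line")
    if regime == "interference":
        mapped = critical_line_point(nsigma) if nsigma > 0 else CriticalLinePoint(
            8.0 / 3.0, 0.0, 0.0
        )
    else:
        mapped = CriticalLinePoint(ns_star=Ns, nu_star=NU, nsigma=nsigma)
    pi_ratio = (
        bsl_reduction_corrected(mapped.ns_star, mapped.nu_star)
        if mapped.nu_star > 0
        else 1.0
    )
    return CoarseGrainedPrediction(
        original=(Ns, NU),
        mapped=mapped,
        regime=regime,
        pi_ratio=pi_ratio,
        diagnostics={"zeta": zeta},
    )


def coarse_grained_pi_ratio(Ns: float, NU: float) -> float:
    """Deterministic coarse-grained ``pi/pi0`` (analytic, no Monte Carlo)."""
    if NU == 0:
        return 1.0
    return coarse_grain_params(Ns, NU).pi_ratio


def predict_asexual(
    Ns: float,
    NU: float,
    N: int,
    n: int,
    reps: int = 10_000,
    seed: int = 0,
) -> CoarseGrainedPrediction:
    """Full coarse-grained prediction for an asexual population.

    Runs the structured coalescent at the mapped parameters (converted to
    per-generation units with ``N``); ``pi_ratio`` is the corrected analytic
    reduction at the mapped point, and the SFS shape and ``t2`` come from
    the coalescent run — mutually consistent within Monte-Carlo error.
    """
    base = coarse_grain_params(Ns, NU)
    m = base.mapped
    effects = []
    if m.nu_star > 0:
        effects.append((m.ns_star / N, m.nu_star / N))
    res = structured_coalescent_expected_sfs(effects, N=N, n=n, reps=reps, seed=seed)
    diag = dict(base.diagnostics)
    diag.update(reps=reps, seed=seed, mc_se_pi=res.mc_se_pi, t2_over_N=res.t2 / N)
    return CoarseGrainedPrediction(
        original=base.original,
        mapped=m,
        regime=base.regime,
        pi_ratio=base.pi_ratio,
        expected_sfs=res.expected_sfs,
        t2=res.t2,
        diagnostics=diag,
    )


def predict_two_effect(
    weak: tuple[float, float],
    strong: tuple[float, float],
    N: int,
    n: int,
    reps: int = 10_000,
    seed: int = 0,
) -> CoarseGrainedPrediction:
    """Coarse-grained prediction for a two-effect (weak + strong) DFE.

    The strongly selected atom acts on the weak mutations mainly through an
    effective population size ``Ne = N e^{-U_st/s_st}``.  The weak atom's
    fitness variance is therefore evaluated at ``Ne`` and mapped to the
    critical line *at Ne*; the resulting coarse-grained weak atom is then
    combined with the unchanged strong atom in the two-class structured
    coalescent at the original ``N``.  Degenerate limits: ``U_st = 0``
    reduces to :func:`predict_asexual` on the weak atom; ``U_w = 0`` to the
    single-effect structured coalescent on the strong atom.
    """
    s_w, U_w = weak
    s_st, U_st = strong
    if U_st == 0:
        return predict_asexual(N * s_w, N * U_w, N=N, n=n, reps=reps, seed=seed)
    lam_st = U_st / s_st
    Ne = N * math.exp(-lam_st)
    diagnostics: dict[str, Any] = {"Ne": Ne, "reps": reps, "seed": seed}
    if classify_regime(N * s_st, N * U_st) != "background":
        msg = "strong atom is not in the background regime on its own"
        logger.warning(msg)
        diagnostics["classification_warning"] = msg
    atoms: list[tuple[float, float]] = [(s_st, U_st)]
    if U_w > 0:
        if classify_regime(Ne * s_w, Ne * U_w) == "interference":
            zeta_w = (Ne * s_w) ** 2 * (Ne * U_w)
            mapped_w = critical_line_point(nsigma_from_zeta(zeta_w))
            s_w_eff, U_w_eff = mapped_w.ns_star / Ne, mapped_w.nu_star / Ne
        else:
            mapped_w = None
            s_w_eff, U_w_eff = s_w, U_w
        atoms.append((s_w_eff, U_w_eff))
        diagnostics["weak_mapped"] = (Ne * s_w_eff, Ne * U_w_eff)
        pi_weak = bsl_reduction_corrected(Ne * s_w_eff, Ne * U_w_eff)
    else:
        pi_weak = 1.0
    res = structured_coalescent_expected_sfs(atoms, N=N, n=n, reps=reps, seed=seed)
    pi_ratio = math.exp(-lam_st) * pi_weak
    Ns_tot = N * math.sqrt(
        (U_w * s_w**2 + U_st * s_st**2) / max(U_w + U_st, 1e-300)
    )
    zeta = Ns_tot**2 * N * (U_w + U_st)
    nsigma = nsigma_from_zeta(zeta)
    mapped_pt = CriticalLinePoint(
        ns_star=N * atoms[-1][0], nu_star=N * atoms[-1][1], nsigma=nsigma
    )
    diagnostics["mc_se_pi"] = res.mc_se_pi
    return CoarseGrainedPrediction(
        original=(N * s_w, N * U_w),
        mapped=mapped_pt,
        regime="interference",
        pi_ratio=pi_ratio,
        expected_sfs=res.expected_sfs,
        t2=res.t2,
        diagnostics=diagnostics,
    )


# re-exported for convenience in examples/tests
__all__ += ["bsl_reduction_first_order", "EULER_GAMMA"]
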