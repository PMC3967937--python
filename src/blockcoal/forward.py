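"""Forward-time Wright-Fisher simulator: the package's ground-truth oracle.

Discrete-generation haploid Wright-Fisher model with multiplicative
selection, an arbitrary discrete distribution of fitness effects, optional
crossover recombination, and an unconstrained (neutral, infinite-sites)
locus at the exact center of the chromosome where the site frequency
spectrum is measured.  Each generation applies, in order: multinomial
reproduction weighted by relative fitness, Poisson(``NR``) single-crossover
recombination events, Poisson(``NU``) selected mutations at random genome
positions, and Poisson(``N U_neutral``) neutral mutations at the center.

A population burns in until the neutral locus develops a most recent common
ancestor (duration ``dt``); thereafter ``samples_per_epoch`` samples of
``n`` individuals are drawn every ``dt`` generations until
``total_generations``.  Fitness variance is estimated both directly
(time-averaged variance of log fitness) and via Fisher's fundamental
theorem from the rate of mean-fitness change.

Two engines share this interface:

* an asexual fast path (``R = 0``) that tracks only per-individual log
  fitness and the neutral-locus haplotype — an exact equivalence for this
  model, since with no recombination genotypes with equal fitness are
  interchangeable;
* a genome-based engine (``R > 0``) carrying explicit mutation lists so
  that crossovers can be performed.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .infinitesimal import DFE
from .sfs import SiteFrequencySpectrum, pairwise_diversity

__all__ = [
    "SimConfig",
    "SimResult",
    "run_wright_fisher",
    "neutral_locus_mrca_reached",
    "estimate_fitness_variance",
    "make_fixture",
    "FIXTURE_PRESETS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a forward-time run (per-generation units)."""

    N: int
    dfe: DFE
    R: float = 0.0
    U_neutral: float | None = None     # defaults to 1/N  (N*U_neutral = 1)
    n: int = 50
    total_generations: int | None = None  # defaults to 20*N
    samples_per_epoch: int = 100
    replicates: int = 1
    seed: int = 0

    def resolved(self) -> "SimConfig":
        out = self
        if out.U_neutral is None:
            out = replace(out, U_neutral=1.0 / out.N)
        if out.total_generations is None:
            out = replace(out, total_generations=20 * out.N)
        return out


@dataclass(frozen=True)
class SimResult:
    """Aggregated output of one or more replicate populations."""

    sfs_samples: list[SiteFrequencySpectrum]
    mean_fitness_trajectory: np.ndarray    # population mean log fitness
    var_fitness_trajectory: np.ndarray     # instantaneous variance of log fitness
    burn_in: int
    sigma_sq_direct: float
    sigma_sq_fisher: float
    pi_ratio: float
    pi_per_replicate: np.ndarray
    sigma_sq_direct_per_replicate: np.ndarray = field(repr=False, default=None)
    sigma_sq_fisher_per_replicate: np.ndarray = field(repr=False, default=None)
    config: SimConfig = field(repr=False, default=None)


def neutral_locus_mrca_reached(lineage_ids: np.ndarray) -> bool:
    """True iff all current neutral-locus ancestry labels coincide."""
    arr = np.asarray(lineage_ids)
    return bool((arr == arr[0]).all())


def _sample_sfs(
    sample_haps: np.ndarray,
    hap_parent: list[int],
    hap_is_mut: list[bool],
    n: int,
) -> SiteFrequencySpectrum:
    """SFS of the neutral locus for one sample, from the haplotype forest."""
    counts: dict[int, int] = {}
    for h in sample_haps:
        h = int(h)
        while h != -1:
            if hap_is_mut[h]:
                counts[h] = counts.get(h, 0) + 1
            h = hap_parent[h]
    xi = np.zeros(n - 1)
    for c in counts.values():
        if 1 <= c <= n - 1:
            xi[c - 1] += 1
    return SiteFrequencySpectrum(n, xi)


def _run_single(cfg: SimConfig, seed: int) -> dict:
    """One replicate population; returns raw per-replicate measurements."""
    rng = np.random.default_rng(seed)
    N = cfg.N
    atoms = [(s, u) for s, u in cfg.dfe.atoms if u > 0]
    U = sum(u for _, u in atoms)
    d_effects = np.array([math.log1p(-s) for s, _ in atoms]) if atoms else np.empty(0)
    d_probs = (
        np.array([u for _, u in atoms]) / U if U > 0 else np.empty(0)
    )
    genomic = cfg.R > 0

    # logw[i] = (sum of log(1-s) over i's current genome) - base;
    # absolute log fitness = logw + base + removed_sum (removed_sum tracks
    # fixed mutations pruned from the genomes for speed)
    logw = np.zeros(N)
    base = 0.0
    removed_sum = 0.0
    hap = np.zeros(N, dtype=np.int64)
    hap_parent: list[int] = [-1]
    hap_is_mut: list[bool] = [False]
    lineage = np.arange(N)
    genomes: list[tuple] = [()] * N if genomic else []

    mean_traj: list[float] = []
    var_traj: list[float] = []
    sfs_samples: list[SiteFrequencySpectrum] = []

    total = cfg.total_generations
    max_burn = total // 2 if N > 1 else 1
    burn_in: int | None = None
    next_sample: int | None = None
    prune_every = 500

    for t in range(1, total + 1):
        # --- reproduction ------------------------------------------------
        w = np.exp(logw - logw.max())
        counts = rng.multinomial(N, w / w.sum())
        parents = np.repeat(np.arange(N), counts)
        logw = logw[parents]
        hap = hap[parents]
        lineage = lineage[parents]
        if genomic:
            genomes = [genomes[p] for p in parents]

        # --- recombination ----------------------------------------------
        if genomic:
            nrec = rng.poisson(N * cfg.R)
            for _ in range(nrec):
                i1 = int(rng.integers(N))
                i2 = int(rng.integers(N - 1))
                if i2 >= i1:
                    i2 += 1
                x = rng.random()
                g1, g2 = genomes[i1], genomes[i2]
                child = tuple(m for m in g1 if m[0] < x) + tuple(
                    m for m in g2 if m[0] >= x
                )
                genomes[i1] = child
                logw[i1] = sum(m[1] for m in child) - base
                if x <= 0.5:  # center locus (0.5) inherited from i2
                    hap[i1] = hap[i2]
                    lineage[i1] = lineage[i2]

        # --- selected mutations ------------------------------------------
        if U > 0:
            nmut = rng.poisson(N * U)
            if nmut:
                idx = rng.integers(0, N, nmut)
                which = (
                    rng.choice(len(atoms), size=nmut, p=d_probs)
                    if len(atoms) > 1
                    else np.zeros(nmut, dtype=int)
                )
                if genomic:
                    pos = rng.random(nmut)
                    for i, j, x in zip(idx, which, pos):
                        d = d_effects[j]
                        g = genomes[i]
                        k = bisect.bisect_left(g, (x,))
                        genomes[i] = g[:k] + ((x, d),) + g[k:]
                        logw[i] += d
                else:
                    np.add.at(logw, idx, d_effects[which])

        # --- neutral mutations at the center locus ------------------------
        nneu = rng.poisson(N * cfg.U_neutral)
        for _ in range(nneu):
            i = int(rng.integers(N))
            hap_parent.append(int(hap[i]))
            hap_is_mut.append(True)
            hap[i] = len(hap_parent) - 1

        # --- bookkeeping --------------------------------------------------
        m = logw.max()
        base += m
        logw -= m
        mean_traj.append(float(logw.mean() + base + removed_sum))
        var_traj.append(float(logw.var()))

        if genomic and t % prune_every == 0:
            # drop deleterious mutations fixed in the whole population
            common = set(genomes[0])
            for g in genomes[1:]:
                common &= set(g)
                if not common:
                    break
            if common:
                genomes = [
                    tuple(mm for mm in g if mm not in common) for g in genomes
                ]
                shift = sum(mm[1] for mm in common)
                logw -= shift
                removed_sum += shift

        if burn_in is None:
            if neutral_locus_mrca_reached(lineage) or t >= max_burn:
                if t >= max_burn and not neutral_locus_mrca_reached(lineage):
                    logger.warning(
                        "burn-in capped at %d generations before MRCA", t
                    )
                burn_in = t
                next_sample = t + max(burn_in, 1)
        elif next_sample is not None and t >= next_sample:
            for _ in range(cfg.samples_per_epoch):
                sample = rng.choice(N, size=min(cfg.n, N), replace=False)
                sfs_samples.append(
                    _sample_sfs(hap[sample], hap_parent, hap_is_mut, cfg.n)
                )
            next_sample = t + max(burn_in, 1)

    if burn_in is None:
        burn_in = total
    return {
        "sfs": sfs_samples,
        "mean_traj": np.array(mean_traj),
        "var_traj": np.array(var_traj),
        "burn_in": burn_in,
    }


def run_wright_fisher(config: SimConfig) -> SimResult:
    """Run ``config.replicates`` independent populations and aggregate."""
    cfg = config.resolved()
    if cfg.N < 1 or cfg.dfe.total_U < 0 or cfg.R < 0 or cfg.U_neutral < 0:
        raise ValueError("invalid simulation configuration")
    all_sfs: list[SiteFrequencySpectrum] = []
    pis: list[float] = []
    mean_trajs = []
    var_trajs = []
    burns = []
    sig_direct = []
    sig_fisher = []
    U = cfg.dfe.total_U
    mean_d = (
        sum(u * math.log1p(-s) for s, u in cfg.dfe.atoms) / U if U > 0 else 0.0
    )
    for r in range(cfg.replicates):
        raw = _run_single(cfg, seed=(cfg.seed + 1_000_003 * r) % (2**31 - 1))
        all_sfs.extend(raw["sfs"])
        if raw["sfs"]:
            pis.append(
                float(np.mean([pairwise_diversity(s) for s in raw["sfs"]]))
            )
        mean_trajs.append(raw["mean_traj"])
        var_trajs.append(raw["var_traj"])
        burns.append(raw["burn_in"])
        post_var = raw["var_traj"][raw["burn_in"]:]
        sig_direct.append(float(post_var.mean()) if post_var.size else 0.0)
        post_mean = raw["mean_traj"][raw["burn_in"]:]
        if post_mean.size > 2:
            v = float(np.polyfit(np.arange(post_mean.size), post_mean, 1)[0])
        else:
            v = 0.0
            logger.warning("trajectory shorter than regression window")
        sig_fisher.append(v - U * mean_d)
    pi0 = 2.0 * cfg.N * cfg.U_neutral
    pi_arr = np.array(pis) if pis else np.array([np.nan])
    return SimResult(
        sfs_samples=all_sfs,
        mean_fitness_trajectory=np.mean(mean_trajs, axis=0),
        var_fitness_trajectory=np.mean(var_trajs, axis=0),
        burn_in=int(np.mean(burns)),
        sigma_sq_direct=float(np.mean(sig_direct)),
        sigma_sq_fisher=float(np.mean(sig_fisher)),
        pi_ratio=float(np.nanmean(pi_arr) / pi0) if pi0 > 0 else float("nan"),
        pi_per_replicate=pi_arr / pi0 if pi0 > 0 else pi_arr,
        sigma_sq_direct_per_replicate=np.array(sig_direct),
        sigma_sq_fisher_per_replicate=np.array(sig_fisher),
        config=cfg,
    )


def estimate_fitness_variance(
    result: SimResult, dfe: DFE, method: str = "direct"
) -> float:
    """Fitness-variance estimate from a finished run.

    ``direct``: time average of the instantaneous population variance of
    log fitness after burn-in.  ``fisher``: Fisher's-fundamental-theorem
    estimate ``sigma^2 = v - U E[delta]``, where ``v`` is the regression
    slope of mean log fitness against time after burn-in and ``E[delta]``
    the mean (signed) log-fitness effect of new mutations — at steady state
    selection (+sigma^2) balances mutation pressure (U E[delta] < 0), and
    any residual slope is Muller's ratchet.
    """
    b = result.burn_in
    if method == "direct":
        post = result.var_fitness_trajectory[b:]
        if post.size == 0:
            raise ValueError("trajectory shorter than the burn-in window")
        return float(post.mean())
    if method == "fisher":
        post = result.mean_fitness_trajectory[b:]
        if post.size < 3:
            raise ValueError("trajectory shorter than the regression window")
        v = float(np.polyfit(np.arange(post.size), post, 1)[0])
        U = dfe.total_U
        mean_d = (
            sum(u * math.log1p(-s) for s, u in dfe.atoms) / U if U > 0 else 0.0
        )
        return v - U * mean_d
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Fixture presets (population-scaled parameters held fixed under scaling)
# ---------------------------------------------------------------------------

#: scaled parameters (Ns, NU, NR) per preset; two_effect lists two atoms.
FIXTURE_PRESETS: dict[str, dict] = {
    "neutral": {"atoms": [], "NR": 0.0},
    "deep_bsl": {"atoms": [(300.0, 30.0)], "NR": 0.0},
    "interference": {"atoms": [(10.0, 100.0)], "NR": 0.0},
    "recombining": {"atoms": [(10.0, 100.0)], "NR": 100.0},
    "two_effect": {"atoms": [(10.0, 100.0), (300.0, 30.0)], "NR": 0.0},
    "dot_chromosome": {"atoms": [(30.0, 300.0)], "NR": 0.0},
}

_BASE_N = 10_000
_fixture_cache: dict[tuple, tuple[SimConfig, SimResult]] = {}


def make_fixture(
    preset: str,
    scale: float = 1.0,
    seed: int = 0,
    n: int = 50,
    replicates: int = 1,
) -> tuple[SimConfig, SimResult]:
    """Run (and cache) a deterministic preset simulation.

    ``scale`` shrinks the population size while holding the scaled
    parameters ``NU, Ns, NR`` fixed, so scaled-parameter comparisons remain
    valid.  Identical ``(preset, scale, seed, n, replicates)`` return the
    identical cached result object.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(FIXTURE_PRESETS)}"
        )
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    key = (preset, float(scale), int(seed), int(n), int(replicates))
    if key in _fixture_cache:
        return _fixture_cache[key]
    spec = FIXTURE_PRESETS[preset]
    N = max(int(round(_BASE_N * scale)), 10)
    dfe = DFE([(Ns / N, NU / N) for Ns, NU in spec["atoms"]])
    cfg = SimConfig(
        N=N,
        dfe=dfe,
        R=spec["NR"] / N,
        n=n,
        replicates=replicates,
        seed=seed,
    )
    result = run_wright_fisher(cfg)
    _fixture_cache[key] = (cfg.resolved(), result)
    return _fixture_cache[key]
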