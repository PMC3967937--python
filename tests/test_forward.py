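"""Forward-time Wright-Fisher simulator."""

import math

import numpy as np
import pytest

import blockcoal as bc
from blockcoal import DFE, SimConfig
from blockcoal.forward import make_fixture, neutral_locus_mrca_reached


class TestNeutralRuns:
    def test_pi_matches_neutral_theory(self):
        """U = 0: E[pi] = 2 N U_neutral within 3 s.e. and D ~ 0."""
        cfg = SimConfig(N=200, dfe=DFE([]), n=20, seed=1, replicates=8,
                        samples_per_epoch=30)
        res = bc.run_wright_fisher(cfg)
        pr = res.pi_per_replicate
        se = pr.std(ddof=1) / math.sqrt(len(pr))
        assert abs(pr.mean() - 1.0) < 3 * se
        xi = np.mean([s.xi for s in res.sfs_samples], axis=0)
        d = bc.tajimas_d(bc.SiteFrequencySpectrum(cfg.n, xi))
        assert abs(d) < 0.6

    def test_neutral_sfs_shape(self):
        """Average neutral SFS is proportional to 1/i across bins."""
        cfg = SimConfig(N=200, dfe=DFE([]), n=10, seed=2, replicates=8,
                        samples_per_epoch=50)
        res = bc.run_wright_fisher(cfg)
        xi = np.mean([s.xi for s in res.sfs_samples], axis=0)
        shape = xi * np.arange(1, 10)
        assert np.all(np.abs(shape / shape.mean() - 1.0) < 0.35)


class TestMRCA:
    def test_single_individual(self):
        assert neutral_locus_mrca_reached(np.array([7]))

    def test_absorbing(self):
        assert neutral_locus_mrca_reached(np.array([3, 3, 3]))
        assert not neutral_locus_mrca_reached(np.array([3, 3, 4]))

    def test_neutral_mrca_time_scales_like_2n(self):
        """Kingman expectation: E[T_MRCA] ~ 2N for a whole-population
        sample."""
        burns = []
        for seed in range(6):
            cfg = SimConfig(N=60, dfe=DFE([]), n=10, seed=seed, replicates=1,
                            samples_per_epoch=1)
            burns.append(bc.run_wright_fisher(cfg).burn_in)
        mean_burn = np.mean(burns)
        assert 0.9 * 60 < mean_burn < 4.5 * 60


class TestSelection:
    def test_deep_background_regime(self):
        """lambda = 0.1 at strong selection: pi/pi0 near e^{-0.1}."""
        N = 400
        cfg = SimConfig(N=N, dfe=DFE([(120.0 / N, 12.0 / N)]), n=20, seed=11,
                        replicates=8, samples_per_epoch=30)
        res = bc.run_wright_fisher(cfg)
        pr = res.pi_per_replicate
        se = pr.std(ddof=1) / math.sqrt(len(pr))
        assert abs(pr.mean() - math.exp(-0.1)) < 3 * se + 0.02

    def test_interference_run_shows_ratchet_and_distortions(self):
        cfg, res = make_fixture("interference", scale=0.05, seed=3, n=30)
        # mean log fitness declines (Muller's ratchet clicks)
        traj = res.mean_fitness_trajectory
        assert traj[-1] < traj[res.burn_in] < 0.0
        xi = np.mean([s.xi for s in res.sfs_samples], axis=0)
        sfs = bc.SiteFrequencySpectrum(30, xi)
        assert bc.tajimas_d(sfs) < 0
        assert bc.mean_minor_allele_freq(sfs) < bc.mean_minor_allele_freq(
            bc.neutral_sfs_expectation(30, 1.0)
        )
        assert bc.ushape_statistic(sfs) > 1.0


class TestFitnessVariance:
    def test_clonal_population_has_zero_variance(self):
        cfg = SimConfig(N=100, dfe=DFE([]), n=10, seed=4, replicates=1,
                        samples_per_epoch=5)
        res = bc.run_wright_fisher(cfg)
        assert bc.estimate_fitness_variance(res, cfg.dfe, "direct") == 0.0
        assert bc.estimate_fitness_variance(res, cfg.dfe, "fisher") == pytest.approx(0.0, abs=1e-12)

    def test_fisher_and_direct_agree(self):
        N = 500
        cfg = SimConfig(N=N, dfe=DFE([(10.0 / N, 100.0 / N)]), n=10, seed=5,
                        replicates=6, samples_per_epoch=5)
        res = bc.run_wright_fisher(cfg)
        d = res.sigma_sq_direct_per_replicate
        f = res.sigma_sq_fisher_per_replicate
        se = math.sqrt(d.var(ddof=1) / len(d) + f.var(ddof=1) / len(f))
        assert abs(d.mean() - f.mean()) < 2 * se + 0.02 * d.mean()

    def test_nearly_neutral_variance_matches_accumulation_rate(self):
        """zeta << 1: sigma^2 ~ N U <s^2> (neutral accumulation over N
        generations)."""
        N = 300
        s, U = 0.3 / N, 3.0 / N   # Ns = 0.3, NU = 3, zeta ~ 0.27
        cfg = SimConfig(N=N, dfe=DFE([(s, U)]), n=10, seed=6, replicates=8,
                        samples_per_epoch=5)
        res = bc.run_wright_fisher(cfg)
        expected = N * U * s * s
        assert res.sigma_sq_direct == pytest.approx(expected, rel=0.35)


class TestEngines:
    def test_asexual_and_genomic_engines_agree(self):
        """R = 0 run through the genome-based engine matches the fast
        class-based engine statistically."""
        N = 150
        a = bc.run_wright_fisher(
            SimConfig(N=N, dfe=DFE([(0.05, 0.05)]), R=0.0, n=15, seed=7,
                      replicates=6, samples_per_epoch=20)
        )
        g = bc.run_wright_fisher(
            SimConfig(N=N, dfe=DFE([(0.05, 0.05)]), R=1e-12, n=15, seed=8,
                      replicates=6, samples_per_epoch=20)
        )
        pa, pg = a.pi_per_replicate, g.pi_per_replicate
        se = math.sqrt(pa.var(ddof=1) / len(pa) + pg.var(ddof=1) / len(pg))
        assert abs(pa.mean() - pg.mean()) < 3 * se + 0.05
        assert abs(a.sigma_sq_direct - g.sigma_sq_direct) < 0.5 * a.sigma_sq_direct + 1e-4

    def test_recombination_restores_diversity(self):
        N = 300
        low = bc.run_wright_fisher(
            SimConfig(N=N, dfe=DFE([(10.0 / N, 100.0 / N)]), R=0.0, n=15,
                      seed=9, replicates=3, samples_per_epoch=20)
        )
        high = bc.run_wright_fisher(
            SimConfig(N=N, dfe=DFE([(10.0 / N, 100.0 / N)]), R=300.0 / N, n=15,
                      seed=10, replicates=3, samples_per_epoch=20)
        )
        assert high.pi_ratio > low.pi_ratio


class TestFixtures:
    def test_presets_resolve_scaled_parameters(self):
        cfg, _ = make_fixture("dot_chromosome", scale=0.01, seed=1, n=10)
        assert cfg.N == 100
        (s, u), = cfg.dfe.atoms
        assert cfg.N * s == pytest.approx(30.0)
        assert cfg.N * u == pytest.approx(300.0)
        assert cfg.R == 0.0

    def test_neutral_preset_has_no_selection(self):
        cfg, _ = make_fixture("neutral", scale=0.01, seed=1, n=10)
        assert cfg.dfe.total_U == 0.0

    def test_fixture_reproducibility(self):
        _, a = make_fixture("neutral", scale=0.02, seed=5, n=10)
        _, b = make_fixture("neutral", scale=0.02, seed=5, n=10)
        assert a is b  # cached
        assert np.array_equal(a.pi_per_replicate, b.pi_per_replicate)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("nope", scale=0.1, seed=0)

    def test_scaled_parameter_invariance(self):
        """pi/pi0 at matched scaled parameters is N-independent within
        combined uncertainty."""
        small = bc.run_wright_fisher(
            SimConfig(N=400, dfe=DFE([(10.0 / 400, 100.0 / 400)]), n=15,
                      seed=12, replicates=5, samples_per_epoch=20)
        )
        big = bc.run_wright_fisher(
            SimConfig(N=800, dfe=DFE([(10.0 / 800, 100.0 / 800)]), n=15,
                      seed=13, replicates=5, samples_per_epoch=20)
        )
        ps, pb = small.pi_per_replicate, big.pi_per_replicate
        se = math.sqrt(ps.var(ddof=1) / len(ps) + pb.var(ddof=1) / len(pb))
        assert abs(ps.mean() - pb.mean()) < 3 * se + 0.03
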