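"""Poisson fitness classes, closed-form reductions, structured coalescent."""

import math

import numpy as np
import pytest

import blockcoal as bc
from blockcoal.bgs import (
    bsl_reduction_asymptotic,
    poisson_class_weights,
    structured_pair_t2,
)


class TestPoissonClassWeights:
    def test_zero_load(self):
        d = poisson_class_weights(0.0)
        assert d.k_max == 0 and d.weights[0] == 1.0

    def test_closed_form_head(self):
        d = poisson_class_weights(2.0)
        assert d.weights[0] == pytest.approx(math.exp(-2.0))
        assert d.weights[1] == pytest.approx(2.0 * math.exp(-2.0))

    @pytest.mark.parametrize("lam", [0.1, 1.0, 7.3, 40.0])
    def test_truncation_contract(self, lam):
        d = poisson_class_weights(lam, tail_tol=1e-8)
        assert d.weights.sum() >= 1.0 - 1e-8
        assert d.weights.shape == (d.k_max + 1,)


class TestClosedFormReductions:
    def test_first_order(self):
        assert bc.bsl_reduction_first_order(0.0) == 1.0
        assert bc.bsl_reduction_first_order(1.0) == pytest.approx(math.exp(-1))
        assert bc.bsl_reduction_first_order(2.3) == pytest.approx(math.exp(-2.3))

    def test_corrected_neutral_limit(self):
        assert bc.bsl_reduction_corrected(5.0, 0.0) == 1.0

    def test_corrected_reaches_first_order_at_strong_selection(self):
        # lambda = 0.1 held fixed, Ns -> infinity
        assert bc.bsl_reduction_corrected(1e4, 1e3) == pytest.approx(
            math.exp(-0.1), abs=1e-3
        )

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.0])
    def test_corrected_converges_to_first_order(self, lam):
        prev_gap = None
        for Ns in (30.0, 300.0, 3000.0):
            gap = abs(bc.bsl_reduction_corrected(Ns, lam * Ns) - math.exp(-lam))
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap

    def test_interior_minimum_at_fixed_nu(self):
        """Slice at constant NU: the corrected reduction dips and recovers,
        with a single interior minimum."""
        grid = np.geomspace(2.0, 300.0, 60)
        vals = np.array([bc.bsl_reduction_corrected(x, 50.0) for x in grid])
        i_min = int(np.argmin(vals))
        assert 0 < i_min < len(grid) - 1
        sign_changes = np.sum(np.diff(np.sign(np.diff(vals))) != 0)
        assert sign_changes == 1

    def test_asymptotic_form_brackets_exact_at_strong_selection(self):
        for Ns, NU in [(300.0, 30.0), (1000.0, 500.0)]:
            exact = bc.bsl_reduction_corrected(Ns, NU)
            approx = bsl_reduction_asymptotic(Ns, NU)
            assert approx == pytest.approx(exact, rel=0.02)

    def test_recombining_limits_and_monotonicity(self):
        U, s = 0.02, 0.002
        assert bc.bsl_reduction_recombining(U, s, 0.0) == pytest.approx(
            bc.bsl_reduction_first_order(U / s)
        )
        assert bc.bsl_reduction_recombining(U, s, 1e6) == pytest.approx(1.0, abs=1e-4)
        grid = [bc.bsl_reduction_recombining(U, s, R) for R in np.geomspace(1e-4, 10, 30)]
        assert np.all(np.diff(grid) >= 0)
        with pytest.raises(ValueError):
            bc.bsl_reduction_recombining(U, -0.1, 0.0)


class TestStructuredCoalescent:
    def test_kingman_limit(self):
        """With no selection the kernel is a Kingman coalescent:
        E[L_i] = 2N/i and E[T2] = N."""
        N, n, reps = 1000, 8, 20_000
        res = bc.structured_coalescent_expected_sfs([], N=N, n=n, reps=reps, seed=42)
        i = np.arange(1, n)
        ratio = res.expected_sfs.xi * i / (2.0 * N)
        assert np.all(np.abs(ratio - 1.0) < 0.05)
        assert res.t2 == pytest.approx(N, rel=0.02)
        d = bc.tajimas_d(res.expected_sfs)
        assert abs(d) < 0.15

    def test_deep_background_regime_matches_first_order(self):
        N = 2000
        res = bc.structured_coalescent_expected_sfs(
            [(300.0 / N, 30.0 / N)], N=N, n=2, reps=30_000, seed=3
        )
        se = res.mc_se_pi / 2.0 / N
        assert abs(res.t2 / N - math.exp(-0.1)) < 3 * se + 1e-3

    def test_matches_exact_pair_solution(self):
        """The MC kernel and the deterministic two-lineage recursion are the
        same model: T2 agrees within Monte-Carlo error."""
        N = 1000
        for Ns, NU in [(40.0, 160.0), (100.0, 100.0)]:
            res = bc.structured_coalescent_expected_sfs(
                [(Ns / N, NU / N)], N=N, n=2, reps=30_000, seed=11
            )
            exact = structured_pair_t2(Ns, NU)
            se = res.mc_se_pi / 2.0 / N
            assert abs(res.t2 / N - exact) < 3.5 * se

    def test_degenerate_second_class_is_exactly_dropped(self):
        N = 500
        a = bc.structured_coalescent_expected_sfs(
            [(0.05, 0.01)], N=N, n=6, reps=300, seed=5
        )
        b = bc.structured_coalescent_expected_sfs(
            [(0.05, 0.01), (0.2, 0.0)], N=N, n=6, reps=300, seed=5
        )
        assert np.array_equal(a.expected_sfs.xi, b.expected_sfs.xi)
        assert a.t2 == b.t2

    def test_seed_reproducibility(self):
        a = bc.structured_coalescent_expected_sfs([(0.05, 0.02)], N=500, n=5, reps=200, seed=9)
        b = bc.structured_coalescent_expected_sfs([(0.05, 0.02)], N=500, n=5, reps=200, seed=9)
        assert np.array_equal(a.expected_sfs.xi, b.expected_sfs.xi)


class TestClassifyRegime:
    def test_printed_parameter_sets(self):
        assert bc.classify_regime(30.0, 300.0) == "interference"
        assert bc.classify_regime(1000.0, 10.0) == "background"

    def test_boundary_point_is_background_by_convention(self):
        p = bc.critical_line_point(25.0)
        assert bc.classify_regime(p.ns_star, p.nu_star) == "background"

    def test_prediction_error_mode(self):
        pred = bc.bsl_reduction_corrected(300.0, 30.0)
        assert (
            bc.classify_regime(300.0, 30.0, mode="prediction_error",
                               observed_pi_ratio=pred * 1.1)
            == "background"
        )
        assert (
            bc.classify_regime(300.0, 30.0, mode="prediction_error",
                               observed_pi_ratio=pred * 0.4)
            == "interference"
        )


def test_population_params_derived_quantities():
    p = bc.PopulationParams(N=1000, dfe=bc.DFE([(0.01, 0.1)]), R=0.05, U_neutral=1e-3)
    assert p.NU == pytest.approx(100.0)
    assert p.NR == pytest.approx(50.0)
    assert p.Ns == pytest.approx(10.0)
    assert p.lam == pytest.approx(10.0)
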