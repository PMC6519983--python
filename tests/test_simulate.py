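import math

import numpy as np
import pytest
from scipy import integrate, stats

from branchnet.core import SimParams
from branchnet.simulate import (
    asymptotic_growth_rate,
    bias_statistic,
    calibrate_to_ratio,
    dimensionless_ratio,
    first_branch_record,
    parameter_scan,
    sample_first_branch,
    sequential_first_branch_oracle,
    simulate_sequential,
    simulate_single_step,
    single_step_first_branch_oracle,
    _sequential_cumhaz,
)


class TestOracles:
    def test_single_step_mean_length_closed_form(self, published_params):
        _, mean_len = single_step_first_branch_oracle(published_params)
        assert mean_len == pytest.approx(math.sqrt(math.pi * 0.09 / 2.2e-3), rel=1e-12)
        assert mean_len == pytest.approx(11.34, abs=0.01)

    def test_single_step_survival_properties(self, published_params):
        S, _ = single_step_first_branch_oracle(published_params)
        assert S(0.0) == pytest.approx(1.0)
        t = np.linspace(0, 500, 100)
        assert (np.diff(S(t)) <= 0).all()

    def test_doubling_k_scales_mean_by_sqrt2(self, published_params):
        _, m1 = single_step_first_branch_oracle(published_params)
        _, m2 = single_step_first_branch_oracle(published_params.replace(k=2 * published_params.k))
        assert m1 / m2 == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_sequential_mean_time_matches_cubic_limit(self, published_params):
        # slow-firing limit: E[T] = (6/(k_bind v k_branch))^(1/3) Gamma(4/3)
        _, mean_t, mean_len = sequential_first_branch_oracle(published_params)
        limit = (6.0 / (0.1 * 0.09 * 2.5e-4)) ** (1 / 3) * math.gamma(4 / 3)
        assert limit == pytest.approx(123.9, abs=0.1)
        assert mean_t == pytest.approx(limit, rel=0.03)
        assert mean_len == pytest.approx(0.09 * mean_t, rel=1e-12)

    def test_sequential_cumhaz_matches_direct_quadrature(self, published_params):
        # independent check of the closed-form cumulative hazard
        kb, ka, v = 0.1, 2.5e-4, 0.09

        def beta(t):
            return kb * v * (t - (1 - math.exp(-ka * t)) / ka)

        for t in (50.0, 124.0, 300.0):
            num, _ = integrate.quad(beta, 0, t)
            assert _sequential_cumhaz(t, kb, ka, v) == pytest.approx(num, rel=1e-8)

    def test_sequential_fast_firing_approaches_single_step(self, published_params):
        p = published_params.replace(k_branch=5.0, dt=0.01)
        S, _, _ = sequential_first_branch_oracle(p)
        t = np.linspace(1, 200, 50)
        expected = np.exp(-0.5 * p.k_bind * p.v_pe * t**2)
        assert np.allclose(S(t), expected, atol=0.02)

    def test_sequential_survival_monotone(self, published_params):
        S, _, _ = sequential_first_branch_oracle(published_params)
        t = np.linspace(0, 1000, 200)
        s = S(t)
        assert s[0] == pytest.approx(1.0)
        assert (np.diff(s) <= 1e-12).all()


class TestGrowthRate:
    def test_single_step_closed_form(self, published_params):
        lam = asymptotic_growth_rate("single_step", published_params)
        assert lam == pytest.approx(math.sqrt(1.1e-3 * 0.09), rel=1e-12)
        assert lam == pytest.approx(9.95e-3, rel=1e-3)

    def test_sequential_root(self, published_params):
        lam = asymptotic_growth_rate("sequential", published_params)
        ka = published_params.k_branch
        assert lam**2 * (lam + ka) == pytest.approx(
            published_params.k_bind * ka * published_params.v_pe, rel=1e-9
        )
        assert lam == pytest.approx(1.30e-2, rel=0.01)

    def test_sequential_fast_firing_limit(self, published_params):
        p = published_params.replace(k_branch=1e4, dt=1e-6)
        lam = asymptotic_growth_rate("sequential", p)
        assert lam == pytest.approx(math.sqrt(p.k_bind * p.v_pe), rel=1e-3)

    def test_long_time_count_slope_matches(self, published_params, rng):
        """Simulated MT count grows exponentially at the analytic rate."""
        lam = asymptotic_growth_rate("single_step", published_params)
        counts = []
        times = None
        for i in range(6):
            net = simulate_single_step(
                published_params.replace(seed=900 + i, t_max=900.0, max_mts=4000)
            )
            ts = np.arange(0, 901, 10.0)
            n = [sum(1 for m in net.mts if m.birth_time <= t) for t in ts]
            counts.append(n)
            times = ts
        mean_n = np.mean(counts, axis=0)
        sel = mean_n > 20
        slope = np.polyfit(times[sel], np.log(mean_n[sel]), 1)[0]
        assert slope == pytest.approx(lam, rel=0.05)


class TestSimulators:
    def test_zero_rate_single_mt(self, published_params):
        net = simulate_single_step(published_params.replace(k=0.0, t_max=100.0))
        assert len(net.mts) == 1
        assert net.mts[0].length(100.0, 0.09) == pytest.approx(9.0)

    def test_zero_branch_rate_accumulates_sites(self, published_params):
        p = published_params.replace(k_branch=0.0, t_max=400.0)
        net = simulate_sequential(p)
        assert len(net.mts) == 1
        assert len(net.sites) > 0
        assert all(s.branch_time is None for s in net.sites)

    def test_expected_site_count_quadratic(self, published_params):
        """E[#sites on a single mother by t] = k_bind * v_pe * t^2 / 2."""
        t_max = 200.0
        expected = 0.1 * 0.09 * t_max**2 / 2.0
        counts = [
            len(
                simulate_sequential(
                    published_params.replace(k_branch=0.0, t_max=t_max, seed=100 + i)
                ).sites
            )
            for i in range(60)
        ]
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(expected, abs=4 * se + 2)

    def test_sequential_sites_fire_at_most_once(self, small_sequential_network):
        fired = [s for s in small_sequential_network.sites if s.branch_time is not None]
        assert len(fired) == len(small_sequential_network.mts) - 1

    def test_ensemble_matches_full_simulator(self, published_params, rng):
        """The vectorized first-branch sampler and the full network simulator
        implement the same per-step recipe."""
        full = []
        for i in range(300):
            net = simulate_sequential(
                published_params.replace(seed=2000 + i, t_max=3000.0, max_mts=2)
            )
            rec = first_branch_record(net)
            if rec is not None:
                full.append(rec.t1)
        fast = sample_first_branch("sequential", published_params, 2000, rng)["t1"]
        assert stats.ks_2samp(full, fast).pvalue > 0.01

    def test_step_size_convergence(self, published_params, rng):
        """Halving dt changes the ensemble mean first-branch length by < 1%."""
        m1 = sample_first_branch(
            "sequential", published_params, 3000, np.random.default_rng(5)
        )
        m2 = sample_first_branch(
            "sequential", published_params.replace(dt=0.5), 3000, np.random.default_rng(6)
        )
        l1 = (m1["d_minus"] + m1["d_plus"]).mean()
        l2 = (m2["d_minus"] + m2["d_plus"]).mean()
        assert abs(l1 - l2) / l1 < 0.015  # 1% + Monte-Carlo allowance


class TestFirstBranch:
    def test_constructed_record(self, published_params):
        from branchnet.core import BranchNetwork, Microtubule

        mts = [
            Microtubule(0, 0.0, (0.0, 0.0), (1.0, 0.0)),
            Microtubule(1, 10 / 0.09, (3.0, 0.0), (1.0, 0.0), 0, 3.0),
        ]
        net = BranchNetwork(published_params, mts, [], t_end=10 / 0.09 + 1)
        rec = first_branch_record(net)
        assert rec.d_minus == pytest.approx(3.0)
        assert rec.d_plus == pytest.approx(7.0)
        assert rec.fraction == pytest.approx(0.3)

    def test_no_branch_returns_none(self, published_params):
        net = simulate_single_step(published_params.replace(k=0.0, t_max=50.0))
        assert first_branch_record(net) is None

    def test_fraction_bounds(self, published_params, rng):
        ens = sample_first_branch("single_step", published_params, 1000, rng)
        assert (ens["fraction"] >= 0).all() and (ens["fraction"] <= 1).all()
        assert np.allclose(
            ens["d_minus"] + ens["d_plus"], 0.09 * ens["t1"], atol=1e-9
        )


class TestDimensionlessRatio:
    def test_paper_value(self, published_params):
        assert dimensionless_ratio(published_params) == pytest.approx(
            2.5e-4 / math.sqrt(0.009), rel=1e-12
        )

    def test_unity(self, published_params):
        p = published_params.replace(k_branch=math.sqrt(0.1 * 0.09), dt=0.01)
        assert dimensionless_ratio(p) == pytest.approx(1.0)

    def test_calibration_preserves_mean_first_branch_length(self, published_params):
        target = sequential_first_branch_oracle(published_params)[2]
        for r in (0.01, 1.0, 50.0):
            p = calibrate_to_ratio(published_params, r)
            assert dimensionless_ratio(p) == pytest.approx(r, rel=1e-6)
            assert sequential_first_branch_oracle(p)[2] == pytest.approx(
                target, rel=1e-4
            )


class TestParameterScan:
    def test_two_regimes(self, published_params, rng):
        """Minus-end bias plateaus for slow firing and vanishes for fast."""
        res = parameter_scan([3e-4, 3e-3, 200.0], published_params, 400, rng)
        biases = {r.ratio: r.bias_statistic for r in res}
        # plateau: further slowing does not increase the bias
        assert biases[3e-4] == pytest.approx(biases[3e-3], abs=0.08)
        assert biases[3e-3] > 0.2
        # fast-firing regime: indistinguishable from the uniform profile
        assert abs(biases[200.0]) < 0.08

    def test_reproducible_within_noise(self, published_params):
        r1 = parameter_scan([1.0], published_params, 400, np.random.default_rng(1))
        r2 = parameter_scan([1.0], published_params, 400, np.random.default_rng(2))
        assert r1[0].bias_statistic == pytest.approx(r2[0].bias_statistic, abs=0.1)

    def test_small_n_warns(self, published_params, rng):
        with pytest.warns(UserWarning, match="noisy"):
            parameter_scan([1.0], published_params, 50, rng)

    def test_bias_statistic_definition(self):
        assert bias_statistic(np.full(100, 0.5)) == pytest.approx(0.0)
        assert bias_statistic(np.zeros(100)) == pytest.approx(1.0)
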