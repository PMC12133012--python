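"""Unit tests for the four monitoring statistics and their state machines."""

import math

import numpy as np
import pytest
from scipy import optimize, special, stats

import ltphrcharts as lc
from ltphrcharts.model import pivotal_draws

N, M = 5, 3


@pytest.fixture
def ref_ic():
    return lc.ICSpec(0.8, 1.0)


class TestLRStatistic:
    def test_zero_at_in_control_point(self, ref_ic):
        est = lc.BatchEstimate(0.8, 1.0)
        assert lc.lr_statistic(est, ref_ic, N, M) == pytest.approx(0.0)

    def test_infinite_below_mu0(self, ref_ic):
        # muhat < mu0 <=> Fbar(muhat) > Fbar(mu0)
        est = lc.BatchEstimate(0.9, 1.0)
        assert lc.lr_statistic(est, ref_ic, N, M) == math.inf

    def test_table10_sample16_value(self, mouse_ic):
        """Hand evaluation for the first shifted batch of the mouse stream:
        d1 = 5*0.5444*ln(0.9587/0.5247), d2 = 0.5444/0.2333,
        LR = 3(d2 - ln d2 - 1) + d1 = 3.0990."""
        est = lc.BatchEstimate(0.5247, 0.2333)
        assert lc.lr_statistic(est, mouse_ic, N, M) == pytest.approx(
            3.09904, abs=1e-4
        )

    def test_monotone_in_sbar_and_convex_in_d2(self, ref_ic):
        lam = 1.3
        sbars = np.linspace(0.05, 0.8, 60)
        vals = [
            lc.lr_statistic(lc.BatchEstimate(s, lam), ref_ic, N, M) for s in sbars
        ]
        assert np.all(np.diff(vals) < 0)  # decreasing in Fbar(muhat)
        d2s = np.geomspace(0.1, 10, 81)
        f = [M * (d - np.log(d) - 1) for d in d2s]
        assert np.argmin(f) == np.argmin(np.abs(d2s - 1.0))
        assert np.all(np.diff(f, 2) > -1e-9)  # convex along the grid

    def test_nonnegative(self, ref_ic, rng):
        sb, lh = pivotal_draws(0.8, 1.0, N, M, rng, size=1000)
        vals = [
            lc.lr_statistic(lc.BatchEstimate(a, b), ref_ic, N, M)
            for a, b in zip(np.clip(sb, 1e-300, 1.0), lh)
        ]
        assert min(vals) >= 0.0


class TestEwmaStep:
    def test_no_smoothing(self):
        assert lc.ewma_step(5.0, 2.0, gamma=1.0) == 2.0

    def test_fixed_point(self):
        v = 3.3
        for _ in range(10):
            v = lc.ewma_step(v, 3.3, gamma=0.2)
        assert v == pytest.approx(3.3)

    def test_forced_arithmetic(self):
        assert lc.ewma_step(2.0271, 0.0, 0.05) == pytest.approx(1.925745)

    def test_infinity_propagates(self):
        assert lc.ewma_step(1.0, math.inf, 0.05) == math.inf


class TestMaxMLEStatistic:
    def test_zero_at_joint_medians(self, ref_ic):
        z1_med = stats.beta.ppf(0.5, N * ref_ic.lambda0, 1)
        z2_med = stats.chi2.ppf(0.5, 2 * M - 2)
        est = lc.BatchEstimate(
            ref_ic.sbar_mu0 * z1_med, 2 * M * ref_ic.lambda0 / z2_med
        )
        assert lc.maxmle_statistic(est, ref_ic, N, M) == pytest.approx(0.0, abs=1e-9)

    def test_in_control_mean_is_two_over_root_pi(self, ref_ic, rng):
        sb, lh = pivotal_draws(0.8, 1.0, N, M, rng, size=100_000)
        vals = [
            lc.maxmle_statistic(lc.BatchEstimate(a, b), ref_ic, N, M)
            for a, b in zip(sb, lh)
        ]
        assert np.mean(vals) == pytest.approx(2 / math.sqrt(math.pi), abs=0.01)

    def test_against_independent_transform(self, mouse_ic, worked_example):
        """Re-derive S for the first mouse batch from scratch: beta cdf is
        z1^(n lam0), chi-square cdf via the regularized lower gamma, then
        standard-normal quantiles."""
        est = worked_example.batches[0]
        z1 = est.sbar_mu_hat / mouse_ic.sbar_mu0
        z2 = 2 * M * mouse_ic.lambda0 / est.lambda_hat
        t1 = stats.norm.ppf(z1 ** (N * mouse_ic.lambda0))
        t2 = stats.norm.ppf(special.gammainc(M - 1, z2 / 2))
        expected = max(abs(t1), abs(t2))
        assert lc.maxmle_statistic(est, mouse_ic, N, M) == pytest.approx(expected)

    def test_finite_when_z1_exceeds_one(self, ref_ic):
        est = lc.BatchEstimate(0.99, 1.0)  # z1 > 1: clipped, stays finite
        v = lc.maxmle_statistic(est, ref_ic, N, M)
        assert np.isfinite(v) and v > 0


class TestMDStatistic:
    def test_zero_at_in_control_point(self, ref_ic):
        assert lc.md_statistic(lc.BatchEstimate(0.8, 1.0), ref_ic) == pytest.approx(0.0)

    def test_analytic_mean_matches_monte_carlo(self, ref_ic, rng):
        """E[MD] = 1/n + E|chi2_{2m-2} - 2m|/(2m), checked for three designs."""
        for n_, m_ in [(5, 3), (10, 6), (15, 12)]:
            analytic = lc.md_start_analytic(n_, m_)
            sb, lh = pivotal_draws(0.8, 1.0, n_, m_, rng, size=200_000)
            mc = np.mean(
                ref_ic.lambda0 * np.abs(np.log(ref_ic.sbar_mu0 / sb))
                + np.abs(ref_ic.lambda0 / lh - 1.0)
            )
            assert mc == pytest.approx(analytic, abs=5e-3)

    def test_start_value_difference_across_n(self):
        """EMD0(n1, m) - EMD0(n2, m) = 1/n1 - 1/n2 (the chi-square part is
        free of n)."""
        d = lc.md_start_analytic(5, 3) - lc.md_start_analytic(10, 3)
        assert d == pytest.approx(1 / 5 - 1 / 10, abs=1e-9)


class TestWLChart:
    def test_first_step_is_gamma_times_lr(self, mouse_ic, worked_example):
        gamma = 0.05
        est = worked_example.batches[0]
        state, wl1 = lc.wl_update(lc.WLState(), est, mouse_ic, gamma, N, M)
        assert state.t == 1
        assert wl1 == pytest.approx(
            gamma * lc.lr_statistic(est, mouse_ic, N, M), rel=1e-12
        )

    def test_zero_on_in_control_stream(self, ref_ic):
        state = lc.WLState()
        est = lc.BatchEstimate(0.8, 1.0)
        for _ in range(10):
            state, wl = lc.wl_update(state, est, ref_ic, 0.1, N, M)
            assert wl == pytest.approx(0.0, abs=1e-12)

    def test_infinite_when_running_min_below_mu0(self, ref_ic):
        state, wl = lc.wl_update(
            lc.WLState(), lc.BatchEstimate(0.9, 1.0), ref_ic, 0.1, N, M
        )
        assert wl == math.inf

    def test_against_numeric_maximization(self, mouse_ic, worked_example):
        """The closed-form WMLEs must reproduce a brute-force maximization
        of the weighted log-likelihood difference at every step of the
        30-batch mouse stream.

        Expressed through the sufficient statistics, the weighted
        log-likelihood difference for a candidate lam (at the optimal
        mu = running minimum, survival scale smax) is

        g(lam) = sum_i w_i [ m ln(lam/lam0)
                             - (lam - lam0) (m/lamhat_i - n ln Fbar(muhat_i))
                             - n (lam ln smax - lam0 ln s0) ].
        """
        gamma = 0.05
        ic = mouse_ic
        batches = worked_example.batches
        state = lc.WLState()
        for t in range(1, len(batches) + 1):
            state, wl = lc.wl_update(state, batches[t - 1], ic, gamma, N, M)
            w = gamma * (1 - gamma) ** np.arange(t - 1, -1, -1)
            sb = np.array([b.sbar_mu_hat for b in batches[:t]])
            lh = np.array([b.lambda_hat for b in batches[:t]])
            smax = sb.max()
            if smax > ic.sbar_mu0:
                assert wl == math.inf
                continue

            def neg_g(lam):
                terms = (
                    M * np.log(lam / ic.lambda0)
                    - (lam - ic.lambda0) * (M / lh - N * np.log(sb))
                    - N * (lam * np.log(smax) - ic.lambda0 * np.log(ic.sbar_mu0))
                )
                return -float(np.sum(w * terms))

            res = optimize.minimize_scalar(
                neg_g, bounds=(1e-3, 50.0), method="bounded",
                options={"xatol": 1e-10},
            )
            assert wl == pytest.approx(-res.fun, abs=1e-6)

    def test_wl_estimates_accessor(self, mouse_ic, worked_example):
        gamma = 0.05
        state = lc.WLState()
        for est in worked_example.batches[:5]:
            state, _ = lc.wl_update(state, est, mouse_ic, gamma, N, M)
        sbar_t, lam_t = lc.wl_estimates(state, gamma, N, M)
        assert sbar_t == max(b.sbar_mu_hat for b in worked_example.batches[:5])
        assert lam_t > 0


class TestRunChart:
    def test_no_signal_with_infinite_limit(self, mouse_ic, worked_example):
        spec = lc.ChartSpec("MD", 0.05, math.inf, 0.6992)
        run = lc.run_chart(worked_example.batches, spec, mouse_ic, N, M)
        assert run.first_signal is None

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            lc.ChartSpec("CUSUM", 0.05, 1.0)

    def test_empty_stream_rejected(self, ref_ic):
        with pytest.raises(ValueError):
            lc.run_chart([], lc.ChartSpec("LR", 0.05, 1.0, 2.0), ref_ic, N, M)

    def test_infinite_statistic_signals_immediately(self, ref_ic):
        # first batch already has muhat < mu0 -> immediate signal
        stream = [lc.BatchEstimate(0.95, 1.0)]
        run = lc.run_chart(stream, lc.ChartSpec("LR", 0.05, 1e12, 2.0), ref_ic, N, M)
        assert run.first_signal == 1

    def test_first_signal_is_minimal(self, mouse_ic, worked_example):
        spec = lc.ChartSpec("WL", 0.05, 0.1141)
        run = lc.run_chart(worked_example.batches, spec, mouse_ic, N, M)
        assert run.first_signal == min(run.signals)

    def test_statistic_invariance_to_ic_parameters(self, rng):
        """The in-control law of every statistic is free of (Fbar(mu0),
        lam0): simulated samples at (0.8, 1) and (0.9587, 0.5444) are
        KS-indistinguishable — this is why calibrated limits carry over
        between parameter settings."""
        draws = 10_000
        out = {}
        for ic in [lc.ICSpec(0.8, 1.0), lc.ICSpec(0.9587, 0.5444)]:
            sb, lh = pivotal_draws(ic.sbar_mu0, ic.lambda0, N, M, rng, size=draws)
            ests = [lc.BatchEstimate(a, b) for a, b in zip(sb, lh)]
            out[ic] = {
                "LR": np.array([lc.lr_statistic(e, ic, N, M) for e in ests]),
                "MaxMLE": np.array([lc.maxmle_statistic(e, ic, N, M) for e in ests]),
                "MD": np.array([lc.md_statistic(e, ic) for e in ests]),
            }
        a, b = out.values()
        for kind in ("LR", "MaxMLE", "MD"):
            assert stats.ks_2samp(a[kind], b[kind]).pvalue > 0.01
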