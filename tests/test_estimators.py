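"""Wald ratios, IVW, MR-Egger (+SIMEX) and the weighted median."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import make_instruments, random_instruments
from mrkit.estimators import (SimexConfig, i2_gx, ivw, mr_egger,
                              ratio_estimates, simex_egger, weighted_median,
                              weighted_median_point)


class TestRatioEstimates:
    def test_identity_ratio(self):
        inst = make_instruments([0.05], [0.001], [0.05], [0.02])
        r = ratio_estimates(inst)[0]
        assert r.theta == pytest.approx(1.0)
        assert r.se_theta == pytest.approx(0.02 / 0.05)

    def test_second_order_dominates_first(self, rng):
        inst = random_instruments(rng, n=30)
        first = ratio_estimates(inst, "first")
        second = ratio_estimates(inst, "second")
        assert all(s.se_theta >= f.se_theta for f, s in zip(first, second))

    def test_weights_normalized(self, instruments):
        w = sum(r.weight for r in ratio_estimates(instruments))
        assert w == pytest.approx(1.0, abs=1e-12)

    def test_zero_gamma_names_snp(self):
        inst = make_instruments([0.05, 0.0], [0.01, 0.01], [0.1, 0.1],
                                [0.02, 0.02], ids=["rsA", "rsB"])
        with pytest.raises(ValueError, match="rsB"):
            ratio_estimates(inst)

    def test_delta_method_against_monte_carlo(self):
        """Second-order delta SE matches the empirical SD of Gamma*/gamma*
        over 10^6 Gaussian draws within 3%."""
        g, sg, G, sG = 0.04, 0.004, 0.02, 0.01
        inst = make_instruments([g], [sg], [G], [sG])
        se2 = ratio_estimates(inst, "second")[0].se_theta
        rng = np.random.default_rng(987)
        draws = (G + rng.standard_normal(1_000_000) * sG) / \
                (g + rng.standard_normal(1_000_000) * sg)
        assert se2 == pytest.approx(float(np.std(draws)), rel=0.03)


class TestIvw:
    def test_single_snp_equals_ratio(self):
        inst = make_instruments([0.05], [0.001], [0.02], [0.01])
        assert ivw(inst).estimate == pytest.approx(0.02 / 0.05)

    def test_equals_fixed_effect_meta_analysis(self, rng):
        """IVW slope is algebraically the inverse-variance-weighted mean of
        the first-order-weighted Wald ratios."""
        for _ in range(20):
            inst = random_instruments(rng, n=int(rng.integers(3, 25)))
            theta = np.array([i.Gamma / i.gamma for i in inst])
            w = np.array([(i.gamma / i.se_Gamma) ** 2 for i in inst])
            oracle = float(np.sum(w * theta) / w.sum())
            assert ivw(inst).estimate == pytest.approx(oracle, abs=1e-10)

    def test_all_zero_gamma_rejected(self):
        inst = make_instruments([0.0, 0.0], [0.01, 0.01], [0.1, 0.2], [0.02, 0.02])
        with pytest.raises(ValueError):
            ivw(inst)

    def test_multiplicative_scale_never_narrower_than_fixed(self, rng):
        for _ in range(10):
            inst = random_instruments(rng, n=15)
            assert ivw(inst).se >= ivw(inst, residual_scale="fixed").se - 1e-15

    def test_sign_flip_invariance(self, rng):
        inst = random_instruments(rng, n=10)
        flip = rng.random(10) < 0.5
        flipped = [replace(i, gamma=-i.gamma, Gamma=-i.Gamma) if f else i
                   for i, f in zip(inst, flip)]
        assert ivw(flipped).estimate == pytest.approx(ivw(inst).estimate, abs=1e-12)

    def test_or_scale_mirror(self, instruments):
        res = ivw(instruments)
        assert res.or_ == pytest.approx(np.exp(res.estimate))
        assert res.or_ci == pytest.approx((np.exp(res.ci_low), np.exp(res.ci_high)))


class TestEgger:
    def test_normal_equations_oracle(self, rng):
        """Slope and intercept solve the 2x2 weighted normal equations."""
        for _ in range(20):
            inst = random_instruments(rng, n=int(rng.integers(3, 25)))
            g = np.abs(np.array([i.gamma for i in inst]))
            G = np.array([i.Gamma for i in inst]) * np.sign([i.gamma for i in inst])
            w = np.array([i.se_Gamma for i in inst]) ** -2.0
            A = np.array([[w.sum(), np.sum(w * g)],
                          [np.sum(w * g), np.sum(w * g * g)]])
            b = np.array([np.sum(w * G), np.sum(w * g * G)])
            icept, slope = np.linalg.solve(A, b)
            res = mr_egger(inst)
            assert res.estimate == pytest.approx(slope, abs=1e-10)
            assert res.intercept == pytest.approx(icept, abs=1e-10)

    def test_needs_three_instruments(self):
        inst = make_instruments([0.05, 0.04], [0.01] * 2, [0.1, 0.2], [0.02] * 2)
        with pytest.raises(ValueError):
            mr_egger(inst)

    def test_zero_gamma_spread_singular(self):
        inst = make_instruments([0.05] * 4, [0.01] * 4, [0.1, 0.2, 0.15, 0.12],
                                [0.02] * 4)
        with pytest.raises(ValueError, match="singular"):
            mr_egger(inst)

    def test_orientation_invariance(self, rng):
        """Jointly flipping (gamma, Gamma) of any subset leaves MR-Egger
        unchanged because instruments are re-oriented internally."""
        inst = random_instruments(rng, n=12)
        flip = rng.random(12) < 0.5
        flipped = [replace(i, gamma=-i.gamma, Gamma=-i.Gamma) if f else i
                   for i, f in zip(inst, flip)]
        a, b = mr_egger(inst), mr_egger(flipped)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)

    def test_intercept_odds_mirror(self, instruments):
        res = mr_egger(instruments)
        assert res.intercept_odds == pytest.approx(np.exp(res.intercept))


class TestI2Gx:
    def test_no_dispersion_gives_zero(self):
        inst = make_instruments([0.05] * 5, [0.01] * 5, [0.1] * 5, [0.02] * 5)
        assert i2_gx(inst) == 0.0

    def test_loop_oracle(self, rng):
        for _ in range(10):
            inst = random_instruments(rng, n=10)
            g = np.abs([i.gamma for i in inst])
            sg = np.array([i.se_gamma for i in inst])
            wg = sg ** -2.0
            gbar = np.sum(wg * g) / wg.sum()
            q = sum((gj - gbar) ** 2 / sgj ** 2 for gj, sgj in zip(g, sg))
            expected = max(0.0, (q - 9) / q)
            assert i2_gx(inst) == pytest.approx(expected, abs=1e-10)

    def test_bounded(self, instruments):
        assert 0.0 <= i2_gx(instruments) < 1.0


class TestSimex:
    def test_reduces_to_egger_without_exposure_error(self, rng):
        import copy
        inst = random_instruments(rng, n=10)
        # bypass the se_gamma > 0 record invariant: the zero-error state is
        # a boundary case meaningful only at the estimator level
        exact = [copy.copy(i) for i in inst]
        for i in exact:
            object.__setattr__(i, "se_gamma", 0.0)
        naive = mr_egger(exact)
        corr = simex_egger(exact, SimexConfig(reps_per_lambda=50, seed=1))
        assert corr.estimate == naive.estimate
        assert corr.intercept == naive.intercept
        assert corr.se == naive.se

    def test_reproducible_given_seed(self, rng):
        inst = random_instruments(rng, n=15)
        cfg = SimexConfig(reps_per_lambda=100, seed=42)
        a = simex_egger(inst, cfg)
        b = simex_egger(inst, SimexConfig(reps_per_lambda=100, seed=42))
        assert a.estimate == b.estimate and a.se == b.se

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimexConfig(lambdas=(0.5, -1.0)).validate()
        with pytest.raises(ValueError):
            SimexConfig(lambdas=(2.0, 1.0)).validate()
        with pytest.raises(ValueError):
            SimexConfig(reps_per_lambda=0).validate()

    def test_corrects_known_attenuation(self):
        """With strong artificial exposure error (I2_GX well below 1) and
        tiny outcome noise, the extrapolated estimate is closer to the
        generating slope than naive MR-Egger in >= 90% of replicates."""
        theta, L = 0.5, 60
        rng = np.random.default_rng(314)
        wins = 0
        n_reps = 100
        for r in range(n_reps):
            g_true = rng.uniform(0.03, 0.10, L)
            se_g = np.full(L, 0.02)
            g_hat = g_true + rng.standard_normal(L) * se_g
            se_G = np.full(L, 0.004)
            G_hat = theta * g_true + rng.standard_normal(L) * se_G
            inst = make_instruments(g_hat, se_g, G_hat, se_G)
            naive = mr_egger(inst).estimate
            corr = simex_egger(inst, SimexConfig(reps_per_lambda=100, seed=r)).estimate
            wins += abs(corr - theta) < abs(naive - theta)
        assert wins / n_reps >= 0.90


class TestWeightedMedian:
    def test_middle_order_statistic(self):
        inst = make_instruments([0.1, 0.1, 0.1], [0.001] * 3,
                                [0.01, 0.05, 0.09], [0.01] * 3)
        assert weighted_median_point(inst) == pytest.approx(0.5)

    def test_brute_force_scan_oracle(self, rng):
        """Matches an independent scan over the cumulative-weight function."""
        for _ in range(30):
            inst = random_instruments(rng, n=7)
            theta = np.array([i.Gamma / i.gamma for i in inst])
            w = np.array([(i.gamma / i.se_Gamma) ** 2 for i in inst])
            order = np.argsort(theta)
            t, ww = theta[order], w[order] / w.sum()
            # independent scan: walk cumulative weights to the 0.5 crossing
            cum = 0.0
            expected = t[-1]
            for j in range(len(t)):
                p_j = cum + ww[j] / 2.0
                if p_j >= 0.5:
                    if j == 0:
                        expected = t[0]
                    else:
                        p_prev = cum - ww[j - 1] + ww[j - 1] / 2.0
                        expected = t[j - 1] + (t[j] - t[j - 1]) * \
                            (0.5 - p_prev) / (p_j - p_prev)
                    break
                cum += ww[j]
            assert weighted_median_point(inst) == pytest.approx(expected, abs=1e-10)

    def test_within_ratio_range(self, rng):
        for _ in range(20):
            inst = random_instruments(rng, n=int(rng.integers(3, 15)))
            theta = [i.Gamma / i.gamma for i in inst]
            est = weighted_median_point(inst)
            assert min(theta) - 1e-12 <= est <= max(theta) + 1e-12

    def test_sign_flip_invariance(self, rng):
        inst = random_instruments(rng, n=9)
        flip = rng.random(9) < 0.5
        flipped = [replace(i, gamma=-i.gamma, Gamma=-i.Gamma) if f else i
                   for i, f in zip(inst, flip)]
        assert weighted_median_point(flipped) == \
            pytest.approx(weighted_median_point(inst), abs=1e-12)

    def test_bootstrap_se_reproducible(self, instruments):
        a = weighted_median(instruments, n_boot=300, seed=5)
        b = weighted_median(instruments, n_boot=300, seed=5)
        assert a.se == b.se and a.estimate == b.estimate

    def test_small_bootstrap_warns(self, instruments):
        with pytest.warns(UserWarning):
            weighted_median(instruments, n_boot=50, seed=1)
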