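import numpy as np
import pytest

from drivephy.exceptions import ValidationError
from drivephy.ou import (
    MODELS,
    OUModel,
    build_covariance,
    build_design,
    loglik,
    simulate_tips,
)
from drivephy.ou import _single_regime_map
from drivephy.phylo import parse_newick, paint_regimes

from conftest import random_painting, random_tree
from oracles import ode_covariance, ode_weights


def _painted(n, seed, depth=1.0):
    t = random_tree(n, seed, depth=depth)
    rm = paint_regimes(t, random_painting(t, seed + 1), "symmetric")
    return t, rm


class TestDesign:
    def test_single_regime_column_of_ones(self):
        t = random_tree(10, 0)
        rm = _single_regime_map(t)
        for a in (0.5, 3.0, 20.0):
            W = build_design(t, rm, a)
            assert np.allclose(W, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_rows_sum_to_one(self, seed):
        t, rm = _painted(12, seed)
        W = build_design(t, rm, [1.7, 0.3])
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_two_tip_closed_form(self):
        t = parse_newick("(A:1,B:1);")
        rm = paint_regimes(t, {"A": "r1", "B": "r1"}, "r1")
        W = build_design(t, rm, 1.0)
        assert W[0, 0] == pytest.approx((1 - np.exp(-1)) + np.exp(-1))

    def test_negative_alpha_rejected(self):
        t = random_tree(5, 1)
        with pytest.raises(ValidationError):
            build_design(t, _single_regime_map(t), -1.0)


class TestCovariance:
    def test_two_tip_star_stationary_increment(self):
        t = parse_newick("(A:1,B:1);")
        rm = _single_regime_map(t)
        V = build_covariance(t, rm, 1.0, 2.0)
        expected = (2.0 / 2.0) * (1 - np.exp(-2.0))
        assert V[0, 0] == pytest.approx(expected)
        assert V[0, 1] == 0.0

    def test_alpha_zero_limit_matches_bm(self):
        t, rm = _painted(8, 7)
        Vou = build_covariance(t, rm, 1e-8, [2.0, 3.0])
        Vbm = build_covariance(t, rm, 0.0, [2.0, 3.0])
        assert np.max(np.abs(Vou - Vbm) / np.abs(Vbm + 1e-12)) < 1e-6

    def test_stationary_root_adds_attenuated_variance(self):
        t = parse_newick("(A:1,B:1);")
        rm = _single_regime_map(t)
        a, s2 = 1.5, 2.0
        Vf = build_covariance(t, rm, a, s2, root_mode="fixed")
        Vs = build_covariance(t, rm, a, s2, root_mode="stationary")
        vroot = s2 / (2 * a)
        assert Vs[0, 1] == pytest.approx(vroot * np.exp(-2 * a))
        assert Vs[0, 0] == pytest.approx(Vf[0, 0] + vroot * np.exp(-2 * a))

    def test_invalid_sigma_rejected(self):
        t = random_tree(5, 2)
        with pytest.raises(ValidationError):
            build_covariance(t, _single_regime_map(t), 1.0, -1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_ode_oracle(self, seed):
        t, rm = _painted(4, seed + 20)
        alphas = np.array([1.3, 0.4])
        sigmas = np.array([0.8, 2.1])
        V = build_covariance(t, rm, alphas, sigmas)
        Vo = ode_covariance(t, rm, alphas, sigmas)
        assert np.max(np.abs(V - Vo)) / np.max(np.abs(Vo)) < 1e-6
        W = build_design(t, rm, alphas)
        Wo = np.stack([ode_weights(t, rm, alphas, tip) for tip in t.tip_ids])
        assert np.max(np.abs(W - Wo)) < 1e-6


class TestLoglik:
    def test_bm_two_tip_closed_form(self):
        t = parse_newick("(A:1,B:1);")
        rm = _single_regime_map(t)
        ll = loglik(t, rm, {"theta": 1.0, "alpha": 0.0, "sigma2": 1.0}, {"A": 0.0, "B": 2.0})
        assert ll == pytest.approx(-np.log(2 * np.pi) - 1.0, abs=1e-10)

    def test_oum_with_equal_thetas_equals_ou1(self):
        t, rm = _painted(10, 30)
        y = simulate_tips(t, rm, {"theta": [1.0, 1.0], "alpha": 2.0, "sigma2": 1.0}, 3)
        p = {"alpha": 2.0, "sigma2": 1.0}
        ll_m = loglik(t, rm, {**p, "theta": [0.7, 0.7]}, y)
        ll_1 = loglik(t, _single_regime_map(t), {**p, "theta": 0.7}, y)
        assert ll_m == pytest.approx(ll_1, abs=1e-10)

    def test_mle_beats_perturbations(self):
        t, rm = _painted(40, 31)
        y = simulate_tips(t, rm, {"theta": [2.0, 0.0], "alpha": 3.0, "sigma2": 1.0}, 4)
        res = OUModel(t, y, regimes=rm, model="OUM").fit()
        rng = np.random.default_rng(5)
        best = res.llf
        for _ in range(100):
            pert = {
                "theta": res.theta * (1 + 0.05 * rng.normal(size=len(res.theta))),
                "alpha": float(res.alphas[0] * np.exp(0.1 * rng.normal())),
                "sigma2": float(res.sigmas[0] * np.exp(0.1 * rng.normal())),
            }
            assert loglik(t, rm, pert, y) <= best + 1e-8


class TestFit:
    def test_bm1_matches_closed_form(self, four_tip):
        y = {"A": 1.0, "B": 2.0, "C": 5.0, "D": 4.0}
        res = OUModel(four_tip, y, model="BM1").fit()
        C = build_covariance(four_tip, _single_regime_map(four_tip), 0.0, 1.0)
        Ci = np.linalg.inv(C)
        yv = np.array([1.0, 2.0, 5.0, 4.0])
        one = np.ones(4)
        mu = (one @ Ci @ yv) / (one @ Ci @ one)
        s2 = (yv - mu) @ Ci @ (yv - mu) / 4
        assert res.theta[0] == pytest.approx(mu, abs=1e-10)
        assert res.sigmas[0] == pytest.approx(s2, rel=1e-10)

    def test_oum_single_regime_collapses_to_ou1(self):
        t = random_tree(60, 40)
        rm = paint_regimes(t, {l: "one" for l in t.tip_labels}, "one")
        y = simulate_tips(t, rm, {"theta": 3.0, "alpha": 2.0, "sigma2": 1.0}, 6)
        r1 = OUModel(t, y, model="OU1").fit()
        rM = OUModel(t, y, regimes=rm, model="OUM").fit()
        assert rM.llf == pytest.approx(r1.llf, abs=1e-6)

    def test_nesting_loglik_ordering(self):
        t, rm = _painted(80, 41)
        y = simulate_tips(t, rm, {"theta": [1.0, 0.0], "alpha": 2.0, "sigma2": 0.7}, 7)
        fits = {
            name: OUModel(t, y, regimes=rm, model=name).fit().llf
            for name in ("OU1", "OUM", "OUMV", "OUMA", "OUMVA")
        }
        tol = 1e-4
        assert fits["OUM"] >= fits["OU1"] - tol
        assert fits["OUMV"] >= fits["OUM"] - tol
        assert fits["OUMA"] >= fits["OUM"] - tol
        assert fits["OUMVA"] >= max(fits["OUMV"], fits["OUMA"]) - tol

    def test_bm1_is_alpha_to_zero_limit_of_ou1(self):
        t = random_tree(30, 42)
        rm = _single_regime_map(t)
        rng = np.random.default_rng(8)
        y = dict(zip(t.tip_labels, rng.normal(size=30)))
        bm = OUModel(t, y, model="BM1").fit()
        # same sigma^2*t parameterization at tiny alpha
        ll_ou = loglik(
            t, rm, {"theta": bm.theta[0], "alpha": 1e-8, "sigma2": bm.sigmas[0]}, y
        )
        assert abs(ll_ou - bm.llf) < 0.01

    def test_ou1_recovery_window(self):
        t = random_tree(200, 43)
        T = t.max_depth()
        rm = _single_regime_map(t)
        y = simulate_tips(t, rm, {"theta": 5.0, "alpha": 2.0 / T, "sigma2": 1.0}, 11)
        res = OUModel(t, y, model="OU1").fit()
        assert 4.5 <= res.theta[0] <= 5.5

    def test_stationary_root_mode_fits(self):
        t, rm = _painted(40, 44)
        y = simulate_tips(
            t, rm, {"theta": [1.0, 0.0], "alpha": 2.0, "sigma2": 0.5}, 12,
            root_mode="stationary",
        )
        fixed = OUModel(t, y, regimes=rm, model="OUM", root_mode="fixed").fit()
        stat = OUModel(t, y, regimes=rm, model="OUM", root_mode="stationary").fit()
        assert np.isfinite(stat.llf) and np.isfinite(fixed.llf)
        assert stat.llf != fixed.llf

    def test_too_few_tips_rejected(self, three_tip):
        with pytest.raises(ValidationError, match="k"):
            OUModel(three_tip, {"A": 1.0, "B": 2.0, "C": 3.0}, model="OU1").fit()

    def test_non_ultrametric_rejected(self):
        t = parse_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValidationError, match="ultrametric"):
            OUModel(t, {"A": 1.0, "B": 2.0, "C": 3.0}, model="BM1")

    def test_parameter_counts(self):
        expected = {"BM1": 2, "BMS": 3, "OU1": 3, "OUM": 4, "OUMV": 5, "OUMA": 5, "OUMVA": 6}
        for name, k in expected.items():
            assert MODELS[name].k(2) == k


class TestSimulate:
    def test_determinism(self):
        t, rm = _painted(15, 50)
        p = {"theta": [1.0, -1.0], "alpha": 2.0, "sigma2": 1.0}
        a = simulate_tips(t, rm, p, 99)
        b = simulate_tips(t, rm, p, 99)
        assert a == b

    def test_sigma_to_zero_gives_deterministic_expectation(self):
        t, rm = _painted(12, 51)
        theta = np.array([2.0, -3.0])
        y = simulate_tips(t, rm, {"theta": theta, "alpha": 3.0, "sigma2": 1e-12}, 1)
        W = build_design(t, rm, 3.0)
        expect = W @ theta
        got = np.array([y[l] for l in t.tip_labels])
        assert np.max(np.abs(got - expect)) < 1e-4

    def test_strong_pull_tip_means_near_optima(self):
        # clade-contiguous painting: each regime occupies whole subtrees, so
        # under alpha*T = 50 every tip has essentially forgotten the other
        # regime by the present
        t = random_tree(200, 52)
        order = [n for n in t.preorder() if t.is_tip(n)]
        tip_states = {
            t.labels[n]: ("symmetric" if i < 100 else "asymmetric")
            for i, n in enumerate(order)
        }
        rm = paint_regimes(t, tip_states, "symmetric")
        T = t.max_depth()
        a = 50.0 / T
        s2 = 1.0
        theta = {"asymmetric": 4.0, "symmetric": -4.0}
        means = {r: [] for r in rm.alphabet}
        tip_reg = {l: rm.branch_regime[n] for n, l in
                   ((n, t.labels[n]) for n in t.tip_ids)}
        for seed in range(100):
            y = simulate_tips(
                t, rm, {"theta": [theta[r] for r in rm.alphabet], "alpha": a, "sigma2": s2}, seed
            )
            for r in rm.alphabet:
                vals = [y[l] for l in t.tip_labels if tip_reg[l] == r]
                means[r].append(np.mean(vals))
        sd_stat = np.sqrt(s2 / (2 * a))
        for r in rm.alphabet:
            n_r = sum(1 for v in tip_reg.values() if v == r)
            assert abs(np.mean(means[r]) - theta[r]) < 3 * sd_stat / np.sqrt(n_r) + 0.05

    def test_sample_covariance_matches_v(self):
        t = parse_newick("((A:0.6,B:0.6):0.4,(C:0.8,D:0.8):0.2);")
        rm = _single_regime_map(t)
        p = {"theta": 0.0, "alpha": 1.2, "sigma2": 2.0}
        V = build_covariance(t, rm, p["alpha"], p["sigma2"])
        rng = np.random.default_rng(7)
        draws = np.array(
            [list(simulate_tips(t, rm, p, rng).values()) for _ in range(2000)]
        )
        S = np.cov(draws.T)
        assert np.max(np.abs(S - V)) / np.max(np.abs(V)) < 0.05
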