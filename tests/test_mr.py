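"""Two-sample MR estimator suite against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import sympy
from scipy import optimize

from lifemr import (
    LN2,
    EffectEstimate,
    HarmonizedPair,
    InstrumentTable,
    ReverseMR,
    SummaryStats,
    ivw,
    mr_egger,
    run_mr_panel,
    scale_to_doubling,
    simulate_summary_stats,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from tests.conftest import make_spec


def make_pair(gamma, big_gamma, se_gamma=None, se_big_gamma=None):
    gamma = np.asarray(gamma, dtype=float)
    big_gamma = np.asarray(big_gamma, dtype=float)
    j = len(gamma)
    return HarmonizedPair(
        snp=np.array([f"rs{i}" for i in range(j)], dtype=object),
        gamma=gamma,
        se_gamma=np.full(j, 0.01) if se_gamma is None else np.asarray(se_gamma),
        big_gamma=big_gamma,
        se_big_gamma=(np.full(j, 0.05) if se_big_gamma is None
                      else np.asarray(se_big_gamma)),
    )


def random_pair(rng, j=None):
    j = j or rng.integers(3, 26)
    gamma = rng.uniform(0.05, 0.4, j) * rng.choice([-1, 1], j)
    theta = rng.normal(0, 0.3)
    se_y = rng.uniform(0.02, 0.1, j)
    big_gamma = theta * gamma + rng.normal(0, se_y)
    return make_pair(gamma, big_gamma, se_gamma=rng.uniform(0.005, 0.02, j),
                     se_big_gamma=se_y)


class TestWaldRatio:
    def test_arithmetic(self):
        pair = make_pair([0.1], [0.05], se_big_gamma=[0.01])
        res = wald_ratio(pair)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        res = wald_ratio(make_pair([0.1], [0.0]))
        assert res.beta == 0.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_pair([0.0], [0.1]))

    def test_second_order_se_matches_symbolic_delta_method(self):
        g, G, sg, sG = sympy.symbols("g G sg sG", positive=True)
        ratio = G / g
        var = (sympy.diff(ratio, G) ** 2 * sG ** 2
               + sympy.diff(ratio, g) ** 2 * sg ** 2)
        vals = {g: 0.12, G: 0.05, sg: 0.015, sG: 0.02}
        expected = float(sympy.sqrt(var.subs(vals)))
        pair = make_pair([0.12], [0.05], se_gamma=[0.015], se_big_gamma=[0.02])
        res = wald_ratio(pair, second_order_se=True)
        assert res.se == pytest.approx(expected, rel=1e-12)


class TestIvw:
    def test_equal_weight_mean(self):
        res = ivw(make_pair([1.0, 1.0], [1.0, 3.0]))
        assert res.beta == pytest.approx(2.0)

    def test_single_snp_falls_back_to_wald(self):
        pair = make_pair([0.1], [0.05], se_big_gamma=[0.01])
        with pytest.warns(UserWarning):
            res = ivw(pair)
        assert res.method == "wald"
        assert res.beta == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pair = random_pair(rng, j=10)
        w = pair.se_big_gamma ** -2

        def loss(b):
            return np.sum(w * (pair.big_gamma - b * pair.gamma) ** 2)

        opt = optimize.minimize_scalar(loss, bounds=(-10, 10), method="bounded",
                                       options={"xatol": 1e-12})
        assert ivw(pair).beta == pytest.approx(opt.x, abs=1e-6)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pair = random_pair(rng)
            assert (ivw(pair).se
                    >= ivw(pair, effects_model="fixed").se - 1e-15)

    def test_heterogeneity_statistic(self):
        pair = make_pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0],
                         se_big_gamma=[1.0, 1.0, 1.0])
        res = ivw(pair)
        assert res.q_stat == pytest.approx(2.0)  # sum (y - 2)^2
        assert res.q_df == 2


class TestEgger:
    def test_exact_interpolation(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        a, b = 0.05, 0.7
        slope, intercept = mr_egger(make_pair(gamma, a + b * gamma))
        assert slope.beta == pytest.approx(b, abs=1e-10)
        assert intercept.beta == pytest.approx(a, abs=1e-10)
        # residuals are zero but the SE inflation factor is floored at 1
        assert slope.q_stat == pytest.approx(0.0, abs=1e-16)
        assert slope.se > 0

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        pair = random_pair(rng, j=8)
        flipped = HarmonizedPair(
            snp=pair.snp,
            gamma=pair.gamma * np.where(np.arange(8) == 2, -1, 1),
            se_gamma=pair.se_gamma,
            big_gamma=pair.big_gamma * np.where(np.arange(8) == 2, -1, 1),
            se_big_gamma=pair.se_big_gamma,
        )
        s1, i1 = mr_egger(pair)
        s2, i2 = mr_egger(flipped)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
        assert i1.beta == pytest.approx(i2.beta, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_least_squares_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        pair = random_pair(rng).oriented()
        X = sm.add_constant(pair.gamma)
        fit = sm.WLS(pair.big_gamma, X, weights=pair.se_big_gamma ** -2).fit()
        slope, intercept = mr_egger(pair)
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_constant_pleiotropy_recovered_with_tiny_ses(self, instrument):
        # theta = 0, alpha_j = c: Egger intercept -> c, slope -> 0;
        # IVW is biased away from zero
        c = 0.03
        spec = make_spec(instrument, theta={"m1": 0.0},
                         pleiotropy={s: c for s in instrument.table["snp"]})
        exp, out = simulate_summary_stats(spec, 10**8, 10**8, seed=5)
        pair = HarmonizedPair.from_summary(instrument, out)
        slope, intercept = mr_egger(pair)
        assert intercept.beta == pytest.approx(c, abs=2e-3)
        assert abs(slope.beta) < 0.02
        assert abs(ivw(pair).beta) > 0.05

    def test_too_few_snps_or_constant_gamma(self):
        with pytest.raises(ValueError):
            mr_egger(make_pair([0.1, 0.2], [0.1, 0.2]))
        with pytest.raises(ValueError):
            mr_egger(make_pair([0.2, 0.2, 0.2], [0.1, 0.2, 0.3]))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        res = weighted_median(make_pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]),
                              n_boot=0)
        assert res.beta == pytest.approx(2.0)

    def test_dominant_instrument_breakdown(self):
        pair = make_pair([1.0, 1.0, 1.0], [5.0, 1.0, 2.0],
                         se_big_gamma=[0.01, 1.0, 1.0])
        res = weighted_median(pair, n_boot=0)
        assert res.beta == pytest.approx(5.0)

    def test_interpolation_formula_frozen_example(self):
        # ratios {1,2,10,11}, weights {.3,.3,.2,.2}: cumulative midpoints
        # {.15,.45,.70,.90} -> interpolate 0.5 between 2 and 10 -> 3.6
        gamma = np.ones(4)
        ratios = np.array([1.0, 2.0, 10.0, 11.0])
        se_y = 1.0 / np.sqrt([0.3, 0.3, 0.2, 0.2])
        res = weighted_median(make_pair(gamma, ratios, se_big_gamma=se_y),
                              n_boot=0)
        assert res.beta == pytest.approx(3.6, abs=1e-12)

    def test_bootstrap_seed_determinism(self):
        rng = np.random.default_rng(7)
        pair = random_pair(rng)
        a = weighted_median(pair, n_boot=200, seed=11)
        b = weighted_median(pair, n_boot=200, seed=11)
        assert a.se == b.se and np.isfinite(a.se)

    def test_too_few_snps(self):
        with pytest.raises(ValueError):
            weighted_median(make_pair([1.0, 1.0], [1.0, 2.0]))


class TestWeightedMode:
    def test_degenerate_cluster(self):
        res = weighted_mode(make_pair([1.0] * 3, [0.7] * 3), n_boot=0)
        assert res.beta == pytest.approx(0.7)

    def test_majority_cluster_found(self):
        gamma = np.ones(10)
        ratios = np.array([0.95, 0.98, 1.0, 1.02, 1.05, 0.97, 1.01,
                           5.0, 5.1, 4.9])
        pair = make_pair(gamma, ratios, se_big_gamma=np.full(10, 0.3))
        res = weighted_mode(pair, n_boot=0)
        assert res.beta == pytest.approx(1.0, abs=0.1)

    def test_matches_fine_grid_kde_argmax(self):
        rng = np.random.default_rng(19)
        pair = random_pair(rng, j=12)
        ratios, ses = pair.wald_ratios()
        w = ses ** -2
        w = w / w.sum()
        sd = np.sqrt(np.sum(w * (ratios - np.sum(w * ratios)) ** 2))
        order = np.argsort(ratios)
        cum = np.cumsum(w[order]) - 0.5 * w[order]
        q1, q3 = np.interp([0.25, 0.75], cum, ratios[order])
        h = 0.9 * min(sd, (q3 - q1) / 1.349) * 12 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200_001)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios) / h) ** 2) @ w
        oracle = grid[np.argmax(dens)]
        res = weighted_mode(pair, n_boot=0)
        assert res.beta == pytest.approx(oracle, abs=(grid[1] - grid[0]) * 2)

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(23)
        pair = random_pair(rng, j=8)
        scaled = HarmonizedPair(
            snp=pair.snp, gamma=pair.gamma, se_gamma=pair.se_gamma,
            big_gamma=pair.big_gamma,
            se_big_gamma=pair.se_big_gamma * 2.0,
        )
        # ratios unchanged, every weight scaled by 1/4 -> same estimate
        a = weighted_mode(pair, n_boot=0)
        b = weighted_mode(scaled, n_boot=0)
        assert a.beta == pytest.approx(b.beta, abs=1e-6)


class TestScaling:
    def test_constant_multiply(self):
        est = EffectEstimate(beta=0.1, se=0.02, n=100, method="ivw")
        scaled = scale_to_doubling(est)
        assert scaled.beta == pytest.approx(0.0693147, abs=1e-7)
        assert scaled.se == pytest.approx(0.02 * LN2)

    def test_zero_fixed_point(self):
        est = EffectEstimate(beta=0.0, se=0.02, n=100, method="ivw")
        assert scale_to_doubling(est).beta == 0.0

    def test_ci_half_width_ratio_is_exactly_ln2(self):
        est = EffectEstimate(beta=0.3, se=0.07, n=10, method="ivw")
        scaled = est.scale_to_doubling()
        before = est.ci_high - est.ci_low
        after = scaled.ci_high - scaled.ci_low
        assert after / before == pytest.approx(LN2, rel=1e-15)

    def test_double_scaling_guard(self):
        est = EffectEstimate(beta=0.1, se=0.02, n=100, method="ivw")
        with pytest.raises(ValueError):
            est.scale_to_doubling().scale_to_doubling()


class TestReverseMRModel:
    def test_single_snp_panel_gives_wald(self, two_snp_instrument):
        inst = InstrumentTable(two_snp_instrument.table.iloc[[0]], apoe_ids=())
        outcome = SummaryStats(pd.DataFrame({
            "snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["G"],
            "beta": [0.05], "se": [0.01], "eaf": [0.3], "n": [1000],
        }))
        results = run_mr_panel(inst, outcome, methods=("ivw",),
                               exclude_apoe="with")
        assert len(results) == 1
        assert results[0].method == "wald"
        assert results[0].beta == pytest.approx(0.5 * LN2)

    def test_with_without_apoe_strata(self, instrument, spec_factory):
        _, out = simulate_summary_stats(spec_factory(), 20_000, 20_000, seed=9)
        res = ReverseMR(instrument, {"m1": out}).fit(
            methods=("ivw",), exclude_apoe="both")
        table = res.table
        assert set(table["stratum"]) == {"with_APOE", "without_APOE"}
        assert table.loc[table.stratum == "with_APOE", "n_snps"].iloc[0] == 25
        assert table.loc[table.stratum == "without_APOE", "n_snps"].iloc[0] == 23

    def test_repeat_run_identical_bootstrap(self, instrument, spec_factory):
        _, out = simulate_summary_stats(spec_factory(), 20_000, 20_000, seed=10)
        model = ReverseMR(instrument, {"m1": out})
        a = model.fit(methods=("weighted_median",), exclude_apoe="with",
                      n_boot=100, seed=4).table
        b = model.fit(methods=("weighted_median",), exclude_apoe="with",
                      n_boot=100, seed=4).table
        pd.testing.assert_frame_equal(a, b)

    def test_all_estimates_scaled(self, instrument, spec_factory):
        _, out = simulate_summary_stats(spec_factory(), 20_000, 20_000, seed=11)
        res = ReverseMR(instrument, {"m1": out}).fit(n_boot=20, seed=0)
        for est in res.estimates:
            if est.method == "egger_intercept":
                assert not est.scaled_by_ln2
            else:
                assert est.scaled_by_ln2
        assert "Reverse MR" in res.summary()

    def test_unknown_method_rejected(self, instrument, spec_factory):
        _, out = simulate_summary_stats(spec_factory(), 1000, 1000, seed=1)
        with pytest.raises(ValueError):
            ReverseMR(instrument, out).fit(methods=("banana",))


class TestHarmonizedPairValidation:
    def test_duplicate_snps_rejected(self):
        with pytest.raises(ValueError):
            HarmonizedPair(snp=np.array(["rs1", "rs1"]),
                           gamma=[0.1, 0.2], se_gamma=[0.01, 0.01],
                           big_gamma=[0.1, 0.2], se_big_gamma=[0.01, 0.01])

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            make_pair([0.1], [0.1], se_big_gamma=[0.0])

    def test_drop_apoe_snps(self):
        pair = make_pair([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        smaller = pair.drop(["rs0"])
        assert smaller.n_snps == 2
        with pytest.raises(ValueError):
            pair.drop(["rs0", "rs1", "rs2"])
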