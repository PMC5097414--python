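"""Pooling engines vs independently coded formula oracles.

The oracles below are deliberately plain re-derivations from the published
formulas (straight loops, no shared code with harmsynth.pooling), plus a
statsmodels cross-check for the inverse-variance routes.
"""

import math

import numpy as np
import pytest
from scipy.stats import norm
from statsmodels.stats.meta_analysis import combine_effects

from harmsynth.data_model import TwoByTwoTable, ValidationError
from harmsynth.effects import EffectEstimate, rr_single
from harmsynth.pooling import (
    ExactConditionalPooler,
    InverseVariancePooler,
    MantelHaenszelPooler,
    heterogeneity,
    pool_exact,
    pool_iv,
    pool_mh_rr,
    pool_tables,
)
from harmsynth.simulate import SimulationConfig, gen_binary_trialset


def oracle_iv(thetas, variances, random_effects):
    """Inverse-variance / DerSimonian-Laird pooling, coded from the formulas."""
    w = [1.0 / v for v in variances]
    mu_fe = sum(wi * t for wi, t in zip(w, thetas)) / sum(w)
    Q = sum(wi * (t - mu_fe) ** 2 for wi, t in zip(w, thetas))
    df = len(thetas) - 1
    C = sum(w) - sum(wi * wi for wi in w) / sum(w)
    tau2 = max(0.0, (Q - df) / C) if random_effects else 0.0
    ws = [1.0 / (v + tau2) for v in variances]
    mu = sum(wi * t for wi, t in zip(ws, thetas)) / sum(ws)
    se = math.sqrt(1.0 / sum(ws))
    z = norm.ppf(0.975)
    return mu, mu - z * se, mu + z * se, Q, tau2


def oracle_mh(tables):
    """Mantel-Haenszel RR and Greenland-Robins variance from the formulas."""
    num = den = psum = 0.0
    for (a, n1, c, n0) in tables:
        N = n1 + n0
        num += a * n0 / N
        den += c * n1 / N
        psum += (n1 * n0 * (a + c) - a * c * N) / N**2
    rr = num / den
    var = psum / (num * den)
    z = norm.ppf(0.975)
    return rr, math.exp(math.log(rr) - z * math.sqrt(var)), math.exp(math.log(rr) + z * math.sqrt(var))


def random_effects_instance(rng, k):
    thetas = rng.normal(0, 0.8, size=k)
    variances = rng.uniform(0.005, 0.5, size=k)
    return [
        EffectEstimate(theta=float(t), var=float(v), scale_tag="smd")
        for t, v in zip(thetas, variances)
    ]


class TestInverseVariance:
    def test_matches_oracle_on_many_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            k = int(rng.integers(2, 12))
            effects = random_effects_instance(rng, k)
            for model, re_flag in (("fixed", False), ("dl_random", True)):
                est = pool_iv(effects, model=model)
                mu, lo, hi, Q, tau2 = oracle_iv(
                    [e.theta for e in effects], [e.var for e in effects], re_flag
                )
                assert est.theta_pooled == pytest.approx(mu, abs=1e-10)
                assert est.ci_low == pytest.approx(lo, abs=1e-10)
                assert est.ci_high == pytest.approx(hi, abs=1e-10)
                assert est.Q == pytest.approx(Q, abs=1e-10)
                if re_flag:
                    assert est.tau2 == pytest.approx(tau2, abs=1e-10)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        effects = random_effects_instance(rng, 8)
        eff = np.array([e.theta for e in effects])
        var = np.array([e.var for e in effects])
        sm = combine_effects(eff, var, method_re="dl")
        fixed = pool_iv(effects, model="fixed")
        random = pool_iv(effects, model="dl_random")
        assert fixed.theta_pooled == pytest.approx(sm.mean_effect_fe, abs=1e-10)
        assert random.theta_pooled == pytest.approx(sm.mean_effect_re, abs=1e-10)
        assert random.tau2 == pytest.approx(sm.tau2, abs=1e-10)
        assert np.allclose(random.weights, sm.weights_rel_re, atol=1e-10)

    def test_single_study_passthrough(self):
        e = EffectEstimate(theta=0.4, var=0.09, scale_tag="smd")
        est = pool_iv([e], model="dl_random")
        z = norm.ppf(0.975)
        assert est.theta_pooled == 0.4
        assert est.ci_low == pytest.approx(0.4 - z * 0.3)
        assert est.tau2 == 0.0 and est.k == 1

    def test_identical_studies_shrink_ci_as_sqrt_k(self):
        e = EffectEstimate(theta=-0.2, var=0.04, scale_tag="smd")
        one = pool_iv([e], model="dl_random")
        nine = pool_iv([e] * 9, model="dl_random")
        assert nine.theta_pooled == pytest.approx(-0.2)
        assert nine.tau2 == 0.0
        width1 = one.ci_high - one.ci_low
        width9 = nine.ci_high - nine.ci_low
        assert width9 == pytest.approx(width1 / 3.0, rel=1e-9)

    def test_dl_with_zero_tau2_equals_fixed(self):
        e = [EffectEstimate(theta=0.1, var=0.05, scale_tag="smd")] * 4
        assert pool_iv(e, model="dl_random").theta_pooled == pool_iv(e, model="fixed").theta_pooled
        assert pool_iv(e, model="dl_random").ci_low == pool_iv(e, model="fixed").ci_low

    def test_mixed_scales_rejected(self):
        bad = [
            EffectEstimate(theta=0.1, var=0.05, scale_tag="smd"),
            EffectEstimate(theta=0.1, var=0.05, scale_tag="log_rr"),
        ]
        with pytest.raises(ValidationError, match="mixed"):
            pool_iv(bad)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            pool_iv([])


class TestHeterogeneity:
    def test_identical_studies_no_heterogeneity(self):
        e = [EffectEstimate(theta=0.3, var=0.02, scale_tag="smd")] * 5
        Q, tau2, I2 = heterogeneity(e)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert tau2 == 0.0 and I2 == 0.0

    def test_two_study_hand_case(self):
        # w = (10, 5); mu = (10*0.5 + 5*(-0.1)) / 15 = 0.3
        e = [
            EffectEstimate(theta=0.5, var=0.1, scale_tag="smd"),
            EffectEstimate(theta=-0.1, var=0.2, scale_tag="smd"),
        ]
        Q, tau2, I2 = heterogeneity(e)
        q_hand = 10 * (0.5 - 0.3) ** 2 + 5 * (-0.1 - 0.3) ** 2
        c_hand = 15 - (100 + 25) / 15
        assert Q == pytest.approx(q_hand, abs=1e-12)
        assert tau2 == pytest.approx((q_hand - 1) / c_hand, abs=1e-12)
        assert I2 == pytest.approx((q_hand - 1) / q_hand * 100, abs=1e-10)

    def test_q_below_df_truncates(self):
        e = [
            EffectEstimate(theta=0.100, var=1.0, scale_tag="smd"),
            EffectEstimate(theta=0.101, var=1.0, scale_tag="smd"),
            EffectEstimate(theta=0.102, var=1.0, scale_tag="smd"),
        ]
        Q, tau2, I2 = heterogeneity(e)
        assert Q < 2 and tau2 == 0.0 and I2 == 0.0


class TestMantelHaenszel:
    def test_single_stratum_is_crude_rr(self):
        est = pool_mh_rr([TwoByTwoTable(10, 100, 5, 100)])
        assert est.ratio == pytest.approx(2.0, rel=1e-12)

    def test_two_identical_strata_same_rr_narrower_ci(self):
        t = TwoByTwoTable(8, 120, 4, 110)
        one = pool_mh_rr([t])
        two = pool_mh_rr([t, t])
        assert two.ratio == pytest.approx(one.ratio, rel=1e-12)
        assert (two.ci_high - two.ci_low) < (one.ci_high - one.ci_low)

    def test_matches_oracle_on_random_strata(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            k = int(rng.integers(1, 8))
            tables = []
            for _ in range(k):
                n1, n0 = int(rng.integers(10, 60)), int(rng.integers(10, 60))
                tables.append(
                    TwoByTwoTable(int(rng.integers(1, n1 // 2)), n1, int(rng.integers(1, n0 // 2)), n0)
                )
            est = pool_mh_rr(tables)
            rr, lo, hi = oracle_mh([t.as_tuple() for t in tables])
            assert est.ratio == pytest.approx(rr, abs=1e-10)
            assert est.ratio_ci[0] == pytest.approx(lo, abs=1e-10)
            assert est.ratio_ci[1] == pytest.approx(hi, abs=1e-10)

    def test_handles_single_zero_without_correction(self):
        est = pool_mh_rr([TwoByTwoTable(0, 50, 3, 50), TwoByTwoTable(4, 80, 2, 80)])
        assert 0 < est.ratio < 10

    def test_all_both_zero_rejected(self):
        with pytest.raises(ValidationError, match="both-zero"):
            pool_mh_rr([TwoByTwoTable(0, 30, 0, 30)])


class TestCrossMethodProperties:
    def test_permutation_invariance(self):
        ts = gen_binary_trialset(SimulationConfig(k=8, seed=99, true_rr=1.5))
        tables = ts.tables()
        rev = list(reversed(tables))
        for method in ("iv_fixed", "dl_random", "mh", "exact_conditional"):
            a = pool_tables(tables, method=method)
            b = pool_tables(rev, method=method)
            assert a.theta_pooled == b.theta_pooled
            assert a.ci_low == b.ci_low and a.ci_high == b.ci_high

    def test_rare_event_or_approximates_rr(self):
        """At 2-3 % risks the exact conditional OR tracks the MH RR closely."""
        rel_errs = []
        for seed in range(30):
            ts = gen_binary_trialset(
                SimulationConfig(k=10, n_range=(200, 600), p0=0.025, true_rr=1.5, seed=3000 + seed)
            )
            mh = pool_tables(ts.tables(), method="mh")
            ex = pool_tables(ts.tables(), method="exact_conditional")
            rel_errs.append(abs(ex.ratio - mh.ratio) / mh.ratio)
        assert np.median(rel_errs) < 0.05
        assert np.mean(np.array(rel_errs) < 0.05) >= 0.8

    def test_estimators_expose_sklearn_params(self):
        pooler = InverseVariancePooler(model="fixed", level=0.9)
        assert pooler.get_params() == {"model": "fixed", "level": 0.9}
        pooler.set_params(model="dl_random")
        e = [EffectEstimate(theta=0.1, var=0.05, scale_tag="smd")] * 3
        assert pooler.fit(e).summary().method_tag == "dl_random"
        mh = MantelHaenszelPooler().fit([TwoByTwoTable(3, 30, 2, 30)])
        assert hasattr(mh, "theta_") and mh.result_.k == 1
        ex = ExactConditionalPooler(level=0.9).fit([TwoByTwoTable(3, 30, 2, 30)])
        assert ex.get_params()["level"] == 0.9

    def test_weights_sum_to_one(self):
        ts = gen_binary_trialset(SimulationConfig(k=6, seed=4))
        for method in ("iv_fixed", "dl_random", "mh", "exact_conditional"):
            est = pool_tables(ts.tables(), method=method)
            assert sum(est.weights) == pytest.approx(1.0, abs=1e-9)
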