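"""Regression models, survival statistics and fixed-effects pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats, optimize

from chipscope import (
    CohortEstimate,
    apoe_bin,
    braak_group_from_stage,
    composite_adnc_score,
    fit_logistic,
    fit_ordinal_logistic,
    fixed_effects_meta,
    gen_cohort,
    kaplan_meier,
    log_rank_test,
    run_stratified_meta,
    se_from_wald_p,
)
from chipscope.simulate import SimConfig


class TestSeFromWaldP:
    @pytest.mark.parametrize(
        "ratio,p,expected_se",
        [(0.69, 0.13, 0.245), (0.51, 0.068, 0.369), (2.0, 0.0455, np.log(2) / 2)],
    )
    def test_reconstruction(self, ratio, p, expected_se):
        assert se_from_wald_p(np.log(ratio), p) == pytest.approx(
            expected_se, abs=5e-3
        )

    @given(
        theta=st.floats(-3, 3).filter(lambda x: abs(x) > 1e-3),
        se=st.floats(0.01, 2.0),
    )
    def test_roundtrip_identity(self, theta, se):
        p = 2 * stats.norm.sf(abs(theta) / se)
        if 0 < p < 1:
            assert se_from_wald_p(theta, p) == pytest.approx(se, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            se_from_wald_p(0.5, 1.0)
        with pytest.raises(ValueError):
            se_from_wald_p(0.0, 0.05)


class TestFixedEffectsMeta:
    def test_two_cohort_shr_pooling(self):
        """Pooling two printed longitudinal estimates (0.69, P 0.13 and
        0.51, P 0.068) via reconstructed SEs gives 0.63, P ~ 0.024."""
        meta = fixed_effects_meta(
            [
                CohortEstimate.from_ratio("CHS", 0.69, "log_shr", p=0.13),
                CohortEstimate.from_ratio("FHS", 0.51, "log_shr", p=0.068),
            ]
        )
        assert round(meta.ratio, 2) == 0.63
        assert meta.p == pytest.approx(0.024, abs=0.002)

    def test_identical_estimates_symmetry(self):
        e = CohortEstimate("a", "log_or", -0.4, se=0.2)
        meta = fixed_effects_meta([e, CohortEstimate("b", "log_or", -0.4, se=0.2)])
        assert meta.pooled_estimate == pytest.approx(-0.4)
        assert meta.pooled_se == pytest.approx(0.2 / np.sqrt(2))

    def test_three_estimate_hand_weighted_mean(self):
        thetas, ses = [-0.2, -0.5, 0.1], [0.1, 0.3, 0.2]
        w = [1 / s**2 for s in ses]
        expected = sum(wi * t for wi, t in zip(w, thetas)) / sum(w)
        meta = fixed_effects_meta(
            [CohortEstimate(f"c{i}", "log_or", t, se=s)
             for i, (t, s) in enumerate(zip(thetas, ses))]
        )
        assert meta.pooled_estimate == pytest.approx(expected, abs=1e-12)
        assert meta.pooled_se == pytest.approx(1 / np.sqrt(sum(w)), abs=1e-12)

    def test_pooled_within_inputs_and_se_smaller(self):
        rng = np.random.default_rng(5)
        ests = [
            CohortEstimate(f"c{i}", "log_or", rng.normal(0, 0.5),
                           se=rng.uniform(0.1, 0.5))
            for i in range(4)
        ]
        meta = fixed_effects_meta(ests)
        thetas = [e.estimate for e in ests]
        assert min(thetas) <= meta.pooled_estimate <= max(thetas)
        assert meta.pooled_se < min(e.se for e in ests)
        assert sum(meta.weights) == pytest.approx(1.0)

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError, match="mixed effect scales"):
            fixed_effects_meta(
                [CohortEstimate("a", "log_or", 0.1, se=0.1),
                 CohortEstimate("b", "log_shr", 0.1, se=0.1)]
            )


class TestLogistic:
    def test_2x2_closed_form(self):
        # a=40 exposed cases, b=60 exposed controls, c=25, d=75
        a, b, c, d = 40, 60, 25, 75
        x = [1] * (a + b) + [0] * (c + d)
        y = [1] * a + [0] * b + [1] * c + [0] * d
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.params["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)

    def test_null_data_small_z(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 300)
            y = rng.integers(0, 2, 300)
            fit = fit_logistic(pd.DataFrame({"x": x}), y)
            z = fit.params["x"] / fit.se["x"]
            hits += abs(z) < 1.96
        assert hits >= 88  # ~95% of null replicates

    def test_separation_raises(self):
        from chipscope import SeparationError

        x = [0] * 20 + [1] * 20
        y = [0] * 20 + [1] * 20
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"x": x}), y)


class TestOrdinal:
    def test_two_level_reduces_to_logistic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
        design = pd.DataFrame({"x": x})
        ord_fit = fit_ordinal_logistic(design, y)
        log_fit = fit_logistic(design, y)
        assert ord_fit.params["x"] == pytest.approx(log_fit.params["x"], abs=1e-6)

    def test_matches_independent_ml_oracle(self):
        """Three-level proportional-odds fit equals an independently coded
        maximum-likelihood optimum."""
        rng = np.random.default_rng(2)
        n = 150
        x = rng.normal(size=n)
        eta = 0.9 * x
        u = rng.random(n)
        c1, c2 = -0.5, 0.7
        p1 = 1 / (1 + np.exp(-(c1 - eta)))
        p2 = 1 / (1 + np.exp(-(c2 - eta)))
        y = np.where(u < p1, 0, np.where(u < p2, 1, 2))

        def negll(params):
            beta, t1, dt = params
            t2 = t1 + np.exp(dt)
            lp = beta * x
            cp1 = 1 / (1 + np.exp(-(t1 - lp)))
            cp2 = 1 / (1 + np.exp(-(t2 - lp)))
            probs = np.select([y == 0, y == 1], [cp1, cp2 - cp1], 1 - cp2)
            return -np.sum(np.log(np.clip(probs, 1e-12, None)))

        oracle = optimize.minimize(
            negll, x0=[0.0, -0.5, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
        )
        fit = fit_ordinal_logistic(pd.DataFrame({"x": x}), y)
        assert fit.params["x"] == pytest.approx(oracle.x[0], abs=1e-4)

    def test_planted_effect_recovery(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 400
            x = rng.normal(size=n)
            eta = np.log(0.50) * x
            u = rng.random(n)
            c1, c2 = -0.7, 0.7
            p1 = 1 / (1 + np.exp(-(c1 - eta)))
            p2 = 1 / (1 + np.exp(-(c2 - eta)))
            y = np.where(u < p1, 0, np.where(u < p2, 1, 2))
            fit = fit_ordinal_logistic(pd.DataFrame({"x": x}), y)
            hits += abs(fit.params["x"] - np.log(0.50)) < 0.3
        assert hits >= 0.9 * n_seeds


class TestCompositeScore:
    @pytest.mark.parametrize(
        "cerad,braak,expected", [(0, 1, 1), (3, 3, 6), (2, 1, 3)]
    )
    def test_examples(self, cerad, braak, expected):
        assert composite_adnc_score(cerad, braak) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            composite_adnc_score(4, 1)
        with pytest.raises(ValueError):
            composite_adnc_score(0, 0)

    @pytest.mark.parametrize(
        "stage,group",
        [(0, 1), (1, 1), (2, 1), (3, 2), (4, 2), (5, 3), (6, 3)],
    )
    def test_braak_grouping(self, stage, group):
        assert braak_group_from_stage(stage) == group


def _hand_logrank(times, events, group):
    """Independent O/E log-rank computation from first principles."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group)
    event_times = np.unique(times[events == 1])
    O = E = V = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == group[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == group[0])).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestSurvival:
    def test_km_no_events_is_flat(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_km_all_events_closed_form(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1]).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3)
        assert km.loc[2.0] == pytest.approx(1 / 3)
        assert km.loc[3.0] == pytest.approx(0.0)

    def test_km_six_subject_hand_table(self):
        # times 1,2,2c,3,4c,5: S = 5/6, 2/3, 4/9, 4/9, 0
        km = kaplan_meier([1, 2, 2, 3, 4, 5], [1, 1, 0, 1, 0, 1])
        km = km.set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(5 / 6)
        assert km.loc[2.0] == pytest.approx(2 / 3)
        assert km.loc[3.0] == pytest.approx(4 / 9)
        assert km.loc[5.0] == pytest.approx(0.0)

    def test_km_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 60)
        km = kaplan_meier(t, np.ones(60, int))
        for time, surv in zip(km["time"], km["survival"]):
            if time > 0:
                assert surv == pytest.approx((t > time).mean(), abs=1e-12)

    def test_km_negative_times_error(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [1, 1])

    def test_logrank_identical_groups_is_null(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1]
        stat, p = log_rank_test(t + t, e + e, [0] * 5 + [1] * 5)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_logrank_matches_hand_table(self):
        times = [2, 3, 5, 7, 8, 10, 12, 14]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        group = [0, 1, 0, 1, 0, 1, 0, 1]
        stat, _ = log_rank_test(times, events, group)
        assert stat == pytest.approx(_hand_logrank(times, events, group), abs=1e-6)

    def test_logrank_group_relabel_invariance(self):
        times = [2, 3, 5, 7, 8, 10, 12, 14]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        group = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        s1, p1 = log_rank_test(times, events, group)
        s2, p2 = log_rank_test(times, events, 1 - group)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_logrank_power_under_planted_hazard_ratio(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(10, 200)
            t1 = rng.exponential(10 / 3, 200)  # hazard ratio 3
            cens = 15.0
            times = np.concatenate([np.minimum(t0, cens), np.minimum(t1, cens)])
            events = np.concatenate([(t0 < cens), (t1 < cens)]).astype(int)
            _, p = log_rank_test(times, events, [0] * 200 + [1] * 200)
            hits += p < 0.01
        assert hits >= 0.95 * n_seeds

    def test_logrank_type_i_error(self):
        """Null rejection rate at alpha = 0.05 stays within 0.05 +/- 0.01."""
        rej = 0
        n_rep = 2000
        rng = np.random.default_rng(123)
        for _ in range(n_rep):
            t = rng.exponential(5, 60)
            e = (rng.random(60) < 0.8).astype(int)
            g = np.repeat([0, 1], 30)
            _, p = log_rank_test(t, e, g)
            rej += p < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.01)


class TestStratified:
    @pytest.mark.parametrize(
        "geno,expected",
        [("e2e3", "low"), ("e2e4", "high"), ("e3e3", "neutral"),
         ("e3e4", "high"), ("e2e2", "low"), ("e4e4", "high")],
    )
    def test_apoe_binning(self, geno, expected):
        assert apoe_bin(geno) == expected

    def test_single_stratum_equals_unstratified(self):
        df = gen_cohort(SimConfig(seed=4, n_subjects=1500))
        res = run_stratified_meta(df, strata_def="all")
        from chipscope.association import _default_design

        fit = fit_logistic(_default_design(df, ("chip", "age", "sex")),
                           df["ad_status"])
        meta = res.per_stratum["all"]
        assert meta.pooled_estimate == pytest.approx(fit.params["chip"])

    def test_planted_heterogeneity_separates_strata(self):
        rng = np.random.default_rng(9)
        n = 4000
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        chip = rng.random(n) < 0.2
        effect = np.where(sex == "female", np.log(0.4), 0.0)
        lp = -0.5 + effect * chip
        df = pd.DataFrame(
            {
                "cohort": np.where(rng.random(n) < 0.5, "A", "B"),
                "age": rng.normal(70, 5, n).round(1),
                "sex": sex,
                "apoe": "e3e3",
                "chip": chip,
                "ad_status": (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int),
            }
        )
        res = run_stratified_meta(df, strata_def="sex")
        assert res.per_stratum["female"].pooled_estimate < \
            res.per_stratum["male"].pooled_estimate - 0.3
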