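"""Contingency odds ratios, logistic models, trend/interaction, spline."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from crpfrail import observational as obs
from crpfrail.pipeline import DEMO_TRANSITION_COUNTS

# published pre-frailty transition counts: (cases, total) per tertile
PROG = DEMO_TRANSITION_COUNTS["progression"]
REG = DEMO_TRANSITION_COUNTS["regression"]


class TestOrFromCounts:
    @pytest.mark.parametrize(
        "exposed, ref, want_or, want_lo, want_hi",
        [
            (PROG["middle"], PROG["low"], 1.28, 1.00, 1.64),
            # Woolf upper bound computes to 2.1025 from these counts
            (PROG["high"], PROG["low"], 1.66, 1.31, 2.10),
            (REG["middle"], REG["low"], 0.90, 0.78, 1.04),
            (REG["high"], REG["low"], 0.76, 0.66, 0.88),
        ],
    )
    def test_published_transition_table(self, exposed, ref, want_or, want_lo, want_hi):
        est = obs.or_from_counts(*exposed, *ref)
        assert est.estimate == pytest.approx(want_or, abs=0.005)
        assert est.ci_low == pytest.approx(want_lo, abs=0.005)
        assert est.ci_high == pytest.approx(want_hi, abs=0.005)

    def test_equal_proportions_give_unit_or(self):
        est = obs.or_from_counts(50, 200, 100, 400)
        assert est.estimate == pytest.approx(1.0)

    def test_zero_cell_requires_haldane(self):
        with pytest.raises(ValueError, match="[Hh]aldane"):
            obs.or_from_counts(0, 50, 10, 50)
        est = obs.or_from_counts(0, 50, 10, 50, haldane=True)
        assert est.estimate < 1

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            obs.or_from_counts(60, 50, 10, 50)
        with pytest.raises(ValueError):
            obs.or_from_counts(-1, 50, 10, 50)

    def test_ci_contains_estimate(self):
        est = obs.or_from_counts(*PROG["high"], *PROG["low"])
        assert est.ci_low <= est.estimate <= est.ci_high


def _counts_to_frame(tiers):
    rows = []
    for level, (c, t) in tiers.items():
        rows += [{"y": 1, "crp_tertile": level}] * c
        rows += [{"y": 0, "crp_tertile": level}] * (t - c)
    return pd.DataFrame(rows)


class TestFitLogistic:
    def test_single_factor_matches_contingency_ors(self):
        for tiers in (PROG, REG):
            df = _counts_to_frame(tiers)
            series = obs.run_model_series(df, "y", models=(1,))
            for level in ("middle", "high"):
                closed = obs.or_from_counts(*tiers[level], *tiers["low"])
                fitted = series.loc[series["level"] == level, "or"].item()
                assert fitted == pytest.approx(closed.estimate, abs=1e-6)

    def test_intercept_only_is_logit_of_rate(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        _, res = obs.fit_logistic(y, pd.DataFrame(index=range(100)))
        assert res.params.iloc[0] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(150):
            x = rng.standard_normal(400)
            y = rng.integers(0, 2, 400).astype(float)
            ests, _ = obs.fit_logistic(y, pd.DataFrame({"x": x}))
            pvals.append(ests[0].p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_separation_detected_with_column_name(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        x = y.copy()
        with pytest.raises(ValueError, match="separation|failed"):
            obs.fit_logistic(y, pd.DataFrame({"perfect": x}))

    def test_missing_covariate_column_reported(self):
        df = _counts_to_frame(PROG)
        with pytest.raises(ValueError, match="age"):
            obs.run_model_series(df, "y", models=(2,))


class TestModelSeries:
    def test_confounder_biases_unadjusted_model_only(self):
        rng = np.random.default_rng(3)
        n = 20_000
        u = rng.standard_normal(n)
        # confounder shifts both tertile membership and outcome; true OR = 1
        tert_score = u + rng.standard_normal(n)
        q = np.quantile(tert_score, [1 / 3, 2 / 3])
        tert = np.where(tert_score < q[0], "low", np.where(tert_score < q[1], "middle", "high"))
        y = (rng.random(n) < 1 / (1 + np.exp(-(-2.0 + 0.8 * u)))).astype(float)
        df = pd.DataFrame({"y": y, "crp_tertile": tert, "u": u})
        series = obs.run_model_series(df, "y", models=(1, 3), adjustments={1: (), 3: ("u",)})
        or1 = series.query("model == 1 and level == 'high'")["or"].item()
        or3 = series.query("model == 3 and level == 'high'")["or"].item()
        assert or1 > 1.5
        assert or3 == pytest.approx(1.0, abs=0.12)

    def test_adjustment_is_noop_when_covariates_independent(self, small_cohort):
        from crpfrail import frailty

        rec = frailty.frailty_records(small_cohort.deficits_w1, small_cohort.deficits_w2)
        df = small_cohort.cohort.copy()
        rng = np.random.default_rng(0)
        df["age"] = rng.normal(60, 9, len(df))  # independent of everything
        df["sex"] = rng.integers(0, 2, len(df))
        df["y"] = (rec["category_w2"] == "frailty").astype(int)
        series = obs.run_model_series(df, "y", models=(1, 2))
        for level in ("middle", "high"):
            o1 = series.query("model == 1 and level == @level")["or"].item()
            o2 = series.query("model == 2 and level == @level")["or"].item()
            assert o2 == pytest.approx(o1, rel=0.05)


class TestTrend:
    def test_published_progression_trend_significant(self):
        p = obs.trend_test_from_counts(
            [PROG[k][0] for k in ("low", "middle", "high")],
            [PROG[k][1] for k in ("low", "middle", "high")],
        )
        assert p < 0.001

    def test_monotone_signal_detected(self):
        df = _counts_to_frame({"low": (50, 1000), "middle": (100, 1000), "high": (200, 1000)})
        assert obs.trend_test(df, "y") < 1e-10

    def test_permuted_labels_null(self):
        rng = np.random.default_rng(1)
        base = _counts_to_frame({"low": (60, 300), "middle": (60, 300), "high": (60, 300)})
        pvals = []
        for _ in range(100):
            df = base.copy()
            df["crp_tertile"] = rng.permutation(df["crp_tertile"].to_numpy())
            pvals.append(obs.trend_test(df, "y"))
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_single_level_rejected(self):
        df = pd.DataFrame({"y": [0, 1, 0], "crp_tertile": ["low"] * 3})
        with pytest.raises(ValueError, match="two"):
            obs.trend_test(df, "y")


class TestSubgroupInteraction:
    @staticmethod
    def _simulate(n, beta_female, beta_male, seed):
        rng = np.random.default_rng(seed)
        sex = rng.integers(0, 2, n)
        tert = rng.choice(["low", "middle", "high"], n)
        x = (tert == "high").astype(float) + 0.5 * (tert == "middle")
        beta = np.where(sex == 1, beta_female, beta_male)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + beta * x)))).astype(float)
        return pd.DataFrame({"y": y, "crp_tertile": tert, "sex": sex})

    def test_identical_strata_identical_ors(self):
        df = self._simulate(4000, 0.5, 0.5, 0)
        half = df.iloc[: len(df) // 2].copy()
        doubled = pd.concat([half.assign(g=0), half.assign(g=1)], ignore_index=True)
        table, _ = obs.subgroup_interaction(doubled, "g", "y", adjustments={3: ()})
        for level in ("middle", "high"):
            ors = table[table["level"] == level]["or"]
            assert ors.nunique() == 1 or ors.max() - ors.min() < 1e-10

    def test_sex_specific_effect_detected(self):
        df = self._simulate(20_000, 1.2, 0.0, 2)
        table, p_int = obs.subgroup_interaction(df, "sex", "y", adjustments={3: ()})
        f = table.query("stratum == 1 and level == 'high'")["or"].item()
        m = table.query("stratum == 0 and level == 'high'")["or"].item()
        assert f > m
        assert p_int < 0.01

    def test_interaction_p_uniform_under_homogeneity(self):
        pvals = []
        for s in range(60):
            df = self._simulate(900, 0.4, 0.4, 100 + s)
            _, p_int = obs.subgroup_interaction(df, "sex", "y", adjustments={3: ()})
            pvals.append(p_int)
        assert kstest(pvals, "uniform").pvalue > 0.005

    def test_empty_stratum_flagged_not_fatal(self):
        df = self._simulate(600, 0.5, 0.5, 3)
        df.loc[df["sex"] == 1, "y"] = 0.0  # no cases in one stratum
        table, _ = obs.subgroup_interaction(df, "sex", "y", adjustments={3: ()})
        flagged = table[table["stratum"] == 1]["flag"]
        assert (flagged != "").all()


class TestSpline:
    @staticmethod
    def _crp(rng, n):
        return np.exp(rng.normal(0.3, 0.9, n))

    def test_or_is_one_at_reference(self):
        rng = np.random.default_rng(0)
        crp = self._crp(rng, 2500)
        y = (rng.random(2500) < 0.2).astype(float)
        res = obs.spline_nonlinearity(
            pd.DataFrame({"y": y, "crp": crp}), "y", grid=np.array([1.46, 0.7, 3.0])
        )
        assert res["odds_ratio"][0] == pytest.approx(1.0, abs=1e-12)

    def test_linear_log_odds_not_flagged(self):
        flags = 0
        for s in range(30):
            rng = np.random.default_rng(200 + s)
            crp = self._crp(rng, 1500)
            y = (rng.random(1500) < 1 / (1 + np.exp(-(-2.5 + 0.15 * crp)))).astype(float)
            res = obs.spline_nonlinearity(pd.DataFrame({"y": y, "crp": crp}), "y")
            flags += res["p_nonlinearity"] < 0.05
        assert flags <= 6  # ~5% expected under the null

    def test_saturating_dose_response_detected(self):
        rng = np.random.default_rng(5)
        crp = self._crp(rng, 3000)
        # risk rises steeply then plateaus: inverted-L on the log-odds scale
        lin = -2.0 + 1.2 * np.minimum(crp, 1.5)
        y = (rng.random(3000) < 1 / (1 + np.exp(-lin))).astype(float)
        res = obs.spline_nonlinearity(pd.DataFrame({"y": y, "crp": crp}), "y")
        assert res["p_nonlinearity"] < 1e-4
        # curve flattens: OR gain from 2->4 mg/L much smaller than 0.5->1.5
        o = res["odds_ratio"]
        g = res["grid"]
        low_rise = o[np.argmin(abs(g - 1.5))] / o[np.argmin(abs(g - 0.5))]
        high_rise = o[np.argmin(abs(g - 4.0))] / o[np.argmin(abs(g - 2.0))]
        assert low_rise > 2 * high_rise

    def test_too_few_distinct_values_rejected(self):
        df = pd.DataFrame({"y": [0, 1] * 10, "crp": [1.0, 2.0] * 10})
        with pytest.raises(ValueError, match="knots"):
            obs.spline_nonlinearity(df, "y")
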