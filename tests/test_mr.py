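"""Two-sample MR: selection, harmonization, estimators, sensitivity."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crpfrail import mr
from crpfrail.synthetic import LdReference, generate_instruments

from conftest import toy_sumstats


class TestSelectInstruments:
    def test_no_significant_snps_is_error(self):
        tab = toy_sumstats(10, seed=1, frac_sig=0.0)
        with pytest.raises(ValueError, match="threshold"):
            mr.select_instruments(tab, None)

    def test_low_ld_pair_both_kept(self):
        tab = toy_sumstats(2, seed=2, frac_sig=1.0)
        tab.loc[:, "CHR"] = 1
        tab.loc[:, "BP"] = [1_000_000, 1_100_000]
        r2 = np.array([[1.0, 0.02], [0.02, 1.0]])  # below the 0.01 rule? no: above
        ld = LdReference.from_r2_matrix(r2, chrom=tab["CHR"], bp=tab["BP"], snp=tab["SNP"])
        kept = mr.select_instruments(tab, ld)
        # r2 = 0.02 >= 0.01, 100 kb apart -> the weaker SNP is pruned
        assert len(kept) == 1
        r2b = np.array([[1.0, 0.005], [0.005, 1.0]])
        ldb = LdReference.from_r2_matrix(r2b, chrom=tab["CHR"], bp=tab["BP"], snp=tab["SNP"])
        assert len(mr.select_instruments(tab, ldb)) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        tab = toy_sumstats(n, seed=seed, frac_sig=0.6)
        A = rng.uniform(-1, 1, (n, n))
        corr = A @ A.T
        d = np.sqrt(np.diag(corr))
        r2 = (corr / np.outer(d, d)) ** 2
        np.fill_diagonal(r2, 1.0)
        r2[tab["CHR"].to_numpy()[:, None] != tab["CHR"].to_numpy()[None, :]] = 0.0
        ld = LdReference.from_r2_matrix(r2, chrom=tab["CHR"], bp=tab["BP"], snp=tab["SNP"])
        kept = mr.select_instruments(tab, ld)

        sig = tab[tab["P"] < 5e-8]
        remaining = set(sig.index)
        expect = []
        for i in sig.sort_values("P").index:
            if i not in remaining:
                continue
            expect.append(tab["SNP"].iloc[i])
            remaining.discard(i)
            for j in list(remaining):
                close = (
                    tab["CHR"].iloc[j] == tab["CHR"].iloc[i]
                    and abs(int(tab["BP"].iloc[j]) - int(tab["BP"].iloc[i])) <= 5_000_000
                )
                if close and r2[i, j] >= 0.01:
                    remaining.discard(j)
        assert sorted(kept["SNP"]) == sorted(expect)

    def test_distance_only_fallback_warns(self):
        tab = toy_sumstats(5, seed=3, frac_sig=1.0)
        with pytest.warns(UserWarning, match="distance-only"):
            mr.select_instruments(tab, None)


def _pair(exp_rows, out_rows):
    cols = ["SNP", "A1", "A2", "EAF", "BETA", "SE"]
    return (
        pd.DataFrame(exp_rows, columns=cols),
        pd.DataFrame(out_rows, columns=cols),
    )


class TestHarmonize:
    def test_ambiguous_palindrome_dropped(self):
        e, o = _pair(
            [["rs1", "A", "T", 0.50, 0.1, 0.01], ["rs2", "A", "G", 0.3, 0.2, 0.01]],
            [["rs1", "A", "T", 0.50, 0.05, 0.02], ["rs2", "A", "G", 0.3, 0.1, 0.02]],
        )
        h = mr.harmonize(e, o)
        assert list(h["SNP"]) == ["rs2"]
        assert h.attrs["palindromic_dropped"] == 1

    def test_swapped_alleles_flip_outcome_sign(self):
        e, o = _pair(
            [["rs1", "A", "G", 0.3, 0.1, 0.01]],
            [["rs1", "G", "A", 0.7, 0.05, 0.02]],
        )
        h = mr.harmonize(e, o)
        assert h["beta_outcome"].iloc[0] == pytest.approx(-0.05)
        assert bool(h["flipped"].iloc[0])

    def test_strand_complement_resolved(self):
        e, o = _pair(
            [["rs1", "A", "G", 0.3, 0.1, 0.01]],
            [["rs1", "T", "C", 0.3, 0.05, 0.02]],
        )
        h = mr.harmonize(e, o)
        assert h["beta_outcome"].iloc[0] == pytest.approx(0.05)

    def test_irreconcilable_alleles_dropped(self):
        e, o = _pair(
            [["rs1", "A", "G", 0.3, 0.1, 0.01], ["rs2", "A", "G", 0.3, 0.1, 0.01]],
            [["rs1", "A", "C", 0.3, 0.05, 0.02], ["rs2", "A", "G", 0.3, 0.1, 0.02]],
        )
        h = mr.harmonize(e, o)
        assert list(h["SNP"]) == ["rs2"]
        assert h.attrs["irreconcilable_dropped"] == 1

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        n = 20
        bases = ["A", "G"]
        e = pd.DataFrame(
            {
                "SNP": [f"rs{i}" for i in range(n)],
                "A1": rng.choice(bases, n),
                "A2": "C",
                "EAF": rng.uniform(0.1, 0.9, n),
                "BETA": rng.normal(0, 0.1, n),
                "SE": 0.01,
            }
        )
        o = e.copy()
        o["BETA"] = rng.normal(0, 0.1, n)
        h1 = mr.harmonize(e, o)
        # feed the harmonized orientation back through as exposure/outcome
        e2 = h1.rename(columns={"effect_allele": "A1", "other_allele": "A2",
                                "beta_exposure": "BETA", "se_exposure": "SE",
                                "eaf": "EAF"})[["SNP", "A1", "A2", "EAF", "BETA", "SE"]]
        o2 = h1.rename(columns={"effect_allele": "A1", "other_allele": "A2",
                                "beta_outcome": "BETA", "se_outcome": "SE",
                                "eaf": "EAF"})[["SNP", "A1", "A2", "EAF", "BETA", "SE"]]
        h2 = mr.harmonize(e2, o2)
        pd.testing.assert_frame_equal(
            h1.sort_values("SNP").reset_index(drop=True)[["SNP", "beta_exposure", "beta_outcome"]],
            h2.sort_values("SNP").reset_index(drop=True)[["SNP", "beta_exposure", "beta_outcome"]],
        )

    def test_generator_truth_reproduced(self, sumstats_pair):
        cfg, ld, exp_tab, out_tab, truth = sumstats_pair
        sub = exp_tab.iloc[:300]
        h = mr.harmonize(sub, out_tab.iloc[:300])
        pos = {s: i for i, s in enumerate(exp_tab["SNP"])}
        idx = [pos[s] for s in h["SNP"]]
        want_by = truth["z2"][idx] * out_tab["SE"].iloc[0]
        np.testing.assert_allclose(h["beta_outcome"].to_numpy(), want_by, atol=1e-12)


class TestIvw:
    def test_single_snp_wald_ratio(self):
        h = pd.DataFrame(
            {"SNP": ["rs1"], "beta_exposure": [0.5], "se_exposure": [0.01],
             "beta_outcome": [0.05], "se_outcome": [0.01]}
        )
        with pytest.warns(UserWarning, match="Wald"):
            est = mr.ivw(h)
        assert est.beta == pytest.approx(0.1)
        assert est.method == "wald_ratio"

    def test_identical_ratios_no_heterogeneity(self):
        h = pd.DataFrame(
            {"beta_exposure": [0.1, 0.2, 0.4], "se_exposure": [0.01] * 3,
             "beta_outcome": [0.02, 0.04, 0.08], "se_outcome": [0.01] * 3}
        )
        fixed, random = mr.ivw(h, "fixed"), mr.ivw(h, "random")
        assert fixed.ancillary["Q"] == pytest.approx(0.0, abs=1e-20)
        assert fixed.beta == pytest.approx(0.2)
        assert fixed.se == random.se

    def test_recovers_causal_effect(self, clean_instruments):
        est = mr.ivw(clean_instruments)
        assert est.ci_low <= 0.06 <= est.ci_high

    def test_z_statistic_standard_normal(self):
        # sampling distribution of (beta_hat - truth) / SE under clean
        # instruments; fixed-effect IVW, strong instruments
        from scipy.stats import kstest

        rng = np.random.default_rng(0)
        zstats = []
        for _ in range(3000):
            k = 15
            bx_true = np.abs(rng.normal(0, 0.1, k))
            sx = np.full(k, 1e-4)
            sy = np.full(k, 0.003)
            bx = bx_true + rng.normal(0, sx[0], k)
            by = 0.06 * bx_true + rng.normal(0, sy[0], k)
            w = (bx / sy) ** 2
            r = by / bx
            beta = (w * r).sum() / w.sum()
            zstats.append((beta - 0.06) * np.sqrt(w.sum()))
        assert kstest(zstats, "norm").pvalue > 1e-3


class TestEgger:
    def test_requires_three_instruments(self):
        h = generate_instruments(2, 0.06, seed=0)
        with pytest.raises(ValueError, match="3"):
            mr.egger(h)

    def test_null_intercept_within_two_se(self):
        # a ~5% miss rate per seed is expected for a 2-SE band
        inside = 0
        for s in range(10):
            a = mr.egger(generate_instruments(200, 0.06, seed=2000 + s)).ancillary
            inside += abs(a["egger_intercept"]) < 2 * a["egger_intercept_se"]
        assert inside >= 8

    def test_directional_pleiotropy_shifts_intercept(self):
        # injected pleiotropy ~ half-normal(0.0125): mean 0.00997
        intercepts = [
            mr.egger(
                generate_instruments(200, 0.06, seed=s, pleiotropy_mode="directional",
                                     pleio_prop=1.0, pleio_scale=0.0125)
            ).ancillary["egger_intercept"]
            for s in range(15)
        ]
        assert np.mean(intercepts) == pytest.approx(0.0125 * np.sqrt(2 / np.pi), rel=0.15)

    def test_constrained_intercept_equals_fixed_ivw(self, clean_instruments):
        c = mr.egger(clean_instruments, constrain_intercept=True)
        f = mr.ivw(clean_instruments, "fixed")
        assert c.beta == pytest.approx(f.beta, abs=1e-10)


class TestMedianAndModes:
    def test_uniform_weights_equal_simple_median(self):
        rng = np.random.default_rng(1)
        ratios = rng.normal(0.1, 0.05, 21)
        w = np.ones(21)
        assert mr._weighted_median_value(ratios, w) == pytest.approx(np.median(ratios))

    def test_all_ratios_equal_every_estimator_returns_it(self):
        h = pd.DataFrame(
            {"beta_exposure": [0.1, 0.2, 0.3, 0.4], "se_exposure": [0.01] * 4,
             "beta_outcome": [0.03, 0.06, 0.09, 0.12], "se_outcome": [0.01] * 4}
        )
        assert mr.ivw(h).beta == pytest.approx(0.3)
        assert mr.weighted_median(h, n_boot=50).beta == pytest.approx(0.3)
        assert mr.simple_mode(h, n_boot=50).beta == pytest.approx(0.3)
        assert mr.weighted_mode(h, n_boot=50).beta == pytest.approx(0.3)

    def test_majority_valid_median_beats_ivw_under_pleiotropy(self):
        wins = 0
        for s in range(20):
            h = generate_instruments(
                200, 0.06, seed=900 + s, pleiotropy_mode="directional",
                pleio_prop=0.4, pleio_scale=0.01,
            )
            bi = mr.ivw(h).beta
            bw = mr.weighted_median(h, n_boot=50, seed=s).beta
            wins += abs(bw - 0.06) < abs(bi - 0.06)
        assert wins >= 18


class TestCochranQ:
    def test_identical_ratios_q_zero(self):
        h = pd.DataFrame(
            {"beta_exposure": [0.1, 0.2], "se_exposure": [0.01] * 2,
             "beta_outcome": [0.01, 0.02], "se_outcome": [0.01] * 2}
        )
        q, p = mr.cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_two_snps_equal_weights_hand_algebra(self):
        # k=2, equal w: Q = w (r1 - r2)^2 / 2
        h = pd.DataFrame(
            {"beta_exposure": [0.2, 0.2], "se_exposure": [0.01] * 2,
             "beta_outcome": [0.02, 0.06], "se_outcome": [0.01] * 2}
        )
        r1, r2 = 0.1, 0.3
        w = (0.2 / 0.01) ** 2
        q, _ = mr.cochran_q(h)
        assert q == pytest.approx(w * (r1 - r2) ** 2 / 2)

    def test_overdispersion_detected(self):
        hits = 0
        for s in range(10):
            h = generate_instruments(100, 0.06, seed=700 + s,
                                     pleiotropy_mode="balanced", pleio_prop=1.0,
                                     pleio_scale=0.005)
            _, p = mr.cochran_q(h)
            hits += p < 0.05
        assert hits >= 8


class TestPresso:
    def test_minimum_simulations_enforced(self):
        h = generate_instruments(20, 0.06, seed=0)
        with pytest.raises(ValueError, match="100"):
            mr.mr_presso(h, n_sim=50)

    def test_injected_outlier_flagged_and_corrected(self):
        h = generate_instruments(20, 0.06, seed=13)
        h.loc[5, "beta_outcome"] += 0.08
        out = mr.mr_presso(h, n_sim=1000, seed=1)
        assert 5 in out["outlier_indices"]
        assert out["global_p"] < 0.05
        assert abs(out["corrected"].beta - 0.06) < abs(out["raw"].beta - 0.06)

    def test_clean_data_global_p_not_small(self):
        small = 0
        for s in range(10):
            h = generate_instruments(20, 0.06, seed=40 + s)
            out = mr.mr_presso(h, n_sim=300, seed=s)
            small += out["global_p"] < 0.05
        assert small <= 2

    def test_deterministic_under_seed(self):
        h = generate_instruments(15, 0.06, seed=3)
        a = mr.mr_presso(h, n_sim=200, seed=9)
        b = mr.mr_presso(h, n_sim=200, seed=9)
        assert a["global_p"] == b["global_p"]
        assert a["outlier_indices"] == b["outlier_indices"]


class TestLeaveOneOut:
    def test_row_per_snp(self):
        h = generate_instruments(3, 0.06, seed=0)
        assert len(mr.leave_one_out(h)) == 3

    def test_homogeneous_instruments_unflagged(self, clean_instruments):
        loo = mr.leave_one_out(clean_instruments)
        assert not loo["flagged"].any()

    def test_single_dominant_outlier_flagged(self):
        h = generate_instruments(12, 0.06, seed=21)
        h.loc[4, "beta_outcome"] += 0.3
        loo = mr.leave_one_out(h)
        assert loo["flagged"].sum() == 1
        assert bool(loo["flagged"].iloc[4])


class TestLikelihoodFamily:
    def test_clean_data_all_agree_with_ivw(self, clean_instruments):
        base = mr.ivw(clean_instruments)
        for fn in (mr.maximum_likelihood, mr.penalized_ivw, mr.mr_raps):
            est = fn(clean_instruments)
            assert abs(est.beta - base.beta) < base.se

    def test_ml_handles_exposure_measurement_error(self):
        # heavy noise in beta_exposure biases the mean ratio toward extremes;
        # the joint likelihood models that noise explicitly
        errs_ml, errs_naive = [], []
        for s in range(15):
            h = generate_instruments(150, 0.1, seed=60 + s,
                                     exposure_noise_inflation=18.0)
            errs_ml.append(abs(mr.maximum_likelihood(h).beta - 0.1))
            errs_naive.append(abs(np.mean(h["beta_outcome"] / h["beta_exposure"]) - 0.1))
        assert np.mean(errs_ml) < np.mean(errs_naive)

    def test_robust_family_beats_ivw_with_outliers(self):
        better_raps = better_pen = 0
        for s in range(10):
            h = generate_instruments(100, 0.06, seed=80 + s,
                                     pleiotropy_mode="directional",
                                     pleio_prop=0.1, pleio_scale=0.03)
            e_ivw = abs(mr.ivw(h, "fixed").beta - 0.06)
            better_raps += abs(mr.mr_raps(h, robust=True).beta - 0.06) < e_ivw
            better_pen += abs(mr.penalized_ivw(h).beta - 0.06) < e_ivw
        assert better_raps >= 7
        assert better_pen >= 7


class TestEquivariance:
    @given(st.floats(min_value=0.2, max_value=5.0))
    @settings(deadline=None, max_examples=15)
    def test_scaling_exposure_scales_estimate_inversely(self, c):
        h = generate_instruments(50, 0.06, seed=99)
        hs = h.copy()
        hs["beta_exposure"] *= c
        hs["se_exposure"] *= c
        for fn in (lambda x: mr.ivw(x), mr.egger, mr.maximum_likelihood,
                   lambda x: mr.weighted_median(x, n_boot=30, seed=1)):
            a, b = fn(h), fn(hs)
            assert b.beta == pytest.approx(a.beta / c, rel=1e-4)


def test_run_mr_suite_reports_pleiotropy_tension():
    h = generate_instruments(60, 0.06, seed=5, pleiotropy_mode="directional",
                             pleio_prop=1.0, pleio_scale=0.02)
    out = mr.run_mr_suite(h, methods=("ivw_mre", "egger"), presso_sim=200, seed=0)
    assert {"Q", "Q_p", "egger_intercept"} <= set(out["sensitivity"])
    assert any("pleiotropy" in w for w in out["sensitivity"]["warnings"])
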