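"""RT filters, last-standard selection, mixed models, VIF and Bayes factors."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcfskit import behaviour
from bcfskit.behaviour import (
    anxiety_effect_correlation,
    apply_rt_filters,
    chisq_model_compare,
    compute_vif,
    fit_lmm,
    fit_rt_lmm,
    jzs_bf_from_t,
    jzs_correlation_bf,
    jzs_paired_bf,
    select_last_standards,
    subject_expectation_effects,
    zscore_rt_within_experiment,
)


def _mk(subject, rts, accuracy="correct", **kw):
    return [
        dict(subject_id=subject, rt=rt, accuracy=accuracy,
             emotion=kw.get("emotion", "neutral"),
             expectation=kw.get("expectation", "expected"),
             block_index=kw.get("block_index", 0),
             trial_index_in_block=i)
        for i, rt in enumerate(rts)
    ]


class TestFilters:
    def test_fast_guess_and_error_removal(self):
        df = pd.DataFrame(
            _mk("s1", [0.4, 0.8, 1.0])
            + _mk("s2", [1.0], accuracy="incorrect")
            + _mk("s3", [np.nan], accuracy="no_response")
        )
        kept, log = apply_rt_filters(df)
        assert set(kept["subject_id"]) == {"s1"}
        assert len(kept) == 2
        reasons = log.set_index("subject_id")["reason"]
        assert "fast_guess" in log[log.subject_id == "s1"]["reason"].values
        assert (log[log.subject_id == "s2"]["reason"] == "incorrect").any()
        assert (log[log.subject_id == "s3"]["reason"] == "no_response").any()

    def test_sd_rule_hand_computed(self):
        # {1.0 x 19, 3.0}: mean 1.1, sd ~0.447 -> 3.0 > mean + 3 sd
        df = pd.DataFrame(_mk("s1", [1.0] * 19 + [3.0]))
        kept, log = apply_rt_filters(df)
        assert len(kept) == 19
        assert (log["reason"] == "sd_outlier").sum() == 1
        assert log.loc[log.reason == "sd_outlier", "rt"].iloc[0] == 3.0

    def test_identical_rts_no_sd_exclusions(self):
        df = pd.DataFrame(_mk("s1", [1.0] * 10))
        kept, log = apply_rt_filters(df)
        assert len(kept) == 10 and (log["reason"] == "sd_outlier").sum() == 0

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(_mk("s1", rng.uniform(0.6, 3, 50))
                          + _mk("s2", rng.uniform(0.6, 3, 50)))
        once, _ = apply_rt_filters(df)
        twice, log2 = apply_rt_filters(once)
        pd.testing.assert_frame_equal(once, twice)
        assert (log2["reason"] != "sd_rule_skipped").sum() == 0

    def test_single_trial_subject_skips_sd_rule(self):
        df = pd.DataFrame(_mk("s1", [1.0]))
        kept, log = apply_rt_filters(df)
        assert len(kept) == 1
        assert (log["reason"] == "sd_rule_skipped").any()


class TestLastStandards:
    def test_enumerated_sequence(self):
        # S S S D S S D -> standards at positions 2 and 5 kept
        exps = ["expected"] * 3 + ["unexpected"] + ["expected"] * 2 + ["unexpected"]
        df = pd.DataFrame([
            dict(subject_id="s1", block_index=0, trial_index_in_block=i,
                 expectation=e, emotion="x", rt=1.0, accuracy="correct")
            for i, e in enumerate(exps)
        ])
        out = select_last_standards(df)
        kept_std = out[out.expectation == "expected"]["trial_index_in_block"].tolist()
        assert kept_std == [2, 5]
        assert (out[out.expectation == "unexpected"]["trial_index_in_block"]
                .tolist() == [3, 6])

    def test_no_deviants_empty_standards(self):
        df = pd.DataFrame([
            dict(subject_id="s1", block_index=0, trial_index_in_block=i,
                 expectation="expected", emotion="x", rt=1.0, accuracy="correct")
            for i in range(5)
        ])
        assert len(select_last_standards(df)) == 0

    def test_full_design_upper_range(self, small_cohort):
        """With no exclusions, each deviant contributes one last standard."""
        trials = small_cohort["trials"].copy()
        trials["accuracy"] = "correct"
        trials["rt"] = trials["rt"].fillna(1.0)
        out = select_last_standards(trials)
        n_dev = (trials["expectation"] == "unexpected").sum()
        assert (out["expectation"] == "unexpected").sum() == n_dev
        assert (out["expectation"] == "expected").sum() == n_dev

    def test_excluded_predecessor_drops_standard(self, small_cohort):
        kept = small_cohort["kept"]
        out = select_last_standards(kept)
        assert (out["expectation"] == "expected").sum() <= (
            out["expectation"] == "unexpected"
        ).sum()


class TestMixedModel:
    def test_balanced_emms_equal_cell_means(self):
        rng = np.random.default_rng(1)
        rows = []
        means = {("neutral", "expected"): 1.9, ("neutral", "unexpected"): 2.0,
                 ("fearful", "expected"): 1.8, ("fearful", "unexpected"): 1.75}
        for s in range(8):
            for (emo, exp_), mu in means.items():
                for _ in range(10):
                    rows.append(dict(subject_id=f"s{s}", emotion=emo,
                                     expectation=exp_,
                                     rt=mu + rng.normal(0, 0.05)))
        df = pd.DataFrame(rows)
        fit = fit_rt_lmm(df)
        cell = df.groupby(["emotion", "expectation"])["rt"].mean()
        for _, row in fit.emms.iterrows():
            assert row["emm"] == pytest.approx(
                cell[(row["emotion"], row["expectation"])], abs=1e-6)
            assert row["ci_low"] < row["emm"] < row["ci_high"]

    def test_matches_r_lme4(self, small_cohort):
        """Fixed effects and t statistics agree with lme4/lmerTest."""
        sel = small_cohort["selected"]
        fit = fit_rt_lmm(sel)
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            csv = os.path.join(d, "d.csv")
            sel.to_csv(csv, index=False)
            script = textwrap.dedent(f"""
                suppressMessages(library(lmerTest))
                d <- read.csv("{csv}")
                d$emotion <- relevel(factor(d$emotion), ref="fearful")
                d$expectation <- relevel(factor(d$expectation), ref="expected")
                m <- lmer(rt ~ emotion*expectation + (1|subject_id), data=d)
                cat(fixef(m), sep="\\n")
                cat(coef(summary(m))[,"t value"], sep="\\n")
            """)
            res = subprocess.run(["Rscript", "-e", script],
                                 capture_output=True, text=True, timeout=120)
        vals = [float(x) for x in res.stdout.split()]
        r_beta, r_t = np.array(vals[:4]), np.array(vals[4:8])
        assert np.allclose(fit.params["beta"].to_numpy(), r_beta, atol=2e-3)
        assert np.allclose(fit.params["t"].to_numpy(), r_t, rtol=0.05, atol=0.05)

    def test_interaction_recovery_sign(self, small_cohort):
        fit = fit_rt_lmm(small_cohort["selected"])
        inter = [n for n in fit.params.index if ":" in n][0]
        # generator: +0.05 (neutral) minus -0.08 (fearful) = +0.13
        assert fit.params.loc[inter, "beta"] > 0
        assert fit.params.loc[inter, "p"] < 0.05

    def test_anxiety_model_three_way_term_present(self, small_cohort):
        sel = zscore_rt_within_experiment(small_cohort["selected"])
        fit = fit_rt_lmm(sel, formula="anxiety")
        three_way = [n for n in fit.params.index if n.count(":") == 2]
        assert len(three_way) == 1
        assert fit.converged

    def test_chisq_identical_models(self, small_cohort):
        sel = small_cohort["selected"]
        f1 = fit_rt_lmm(sel, reml=False)
        chi2, df, p = chisq_model_compare(f1, f1)
        assert chi2 == 0 and df == 0 and p == 1.0

    def test_chisq_nested_models(self, small_cohort):
        sel = small_cohort["selected"]
        full = fit_rt_lmm(sel, reml=False)
        null = fit_lmm(sel, "1", response="rt", reml=False)
        chi2, df, p = chisq_model_compare(full, null)
        assert df == 3
        assert chi2 == pytest.approx(2 * (full.loglike - null.loglike))
        assert 0 <= p <= 1

    def test_chisq_rejects_reml(self, small_cohort):
        sel = small_cohort["selected"]
        with pytest.raises(ValueError, match="ML"):
            chisq_model_compare(fit_rt_lmm(sel), fit_rt_lmm(sel))


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": [1, 1, -1, -1] * 10, "b": [1, -1, 1, -1] * 10})
        out = compute_vif(X)
        assert np.allclose(out["vif"], 1.0)

    def test_closed_form_two_correlated(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4000)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.standard_normal(4000)
        out = compute_vif(pd.DataFrame({"x": x, "y": y}))
        r = np.corrcoef(x, y)[0, 1]
        expect = 1.0 / (1.0 - r**2)
        assert np.allclose(out["vif"], expect, rtol=1e-6)

    def test_duplicated_predictor_errors(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinearity"):
            compute_vif(pd.DataFrame({"x": x, "x2": x}))


class TestBayesFactors:
    def test_jzs_null_large_n_supports_null(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        y = x + rng.standard_normal(200) * 0.5
        # zero mean difference by construction
        y = y - (y - x).mean()
        assert jzs_paired_bf(x, y) < 1

    @pytest.mark.parametrize("t,n", [(0.3, 10), (1.5, 25), (2.8, 40), (-2.0, 12),
                                     (4.5, 60), (0.0, 30)])
    def test_jzs_matches_quadrature_oracle(self, t, n):
        """Agreement with an independent noncentral-t grid quadrature."""
        nu = n - 1
        delta = np.linspace(-15, 15, 30001)
        prior = stats.cauchy.pdf(delta, 0, 0.707)
        like = stats.nct.pdf(t, nu, delta * np.sqrt(n))
        oracle = np.trapezoid(like * prior, delta) / stats.t.pdf(t, nu)
        assert jzs_bf_from_t(t, n) == pytest.approx(oracle, rel=0.01)

    def test_jzs_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(2.0, 15), (3.1, 33)]:
            assert jzs_bf_from_t(t, n) == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True)), rel=1e-6)

    def test_correlation_bf_matches_pingouin(self):
        import pingouin as pg

        for r, n in [(0.438, 63), (0.165, 63), (0.05, 200), (0.9, 10)]:
            assert jzs_correlation_bf(r, n) == pytest.approx(
                float(pg.bayesfactor_pearson(r, n)), rel=1e-6)

    def test_correlation_bf_sign_symmetric_and_extremes(self):
        assert jzs_correlation_bf(0.4, 30) == pytest.approx(
            jzs_correlation_bf(-0.4, 30))
        assert jzs_correlation_bf(1.0, 20) == np.inf


class TestAnxietyCorrelation:
    def test_perfect_negative_linear(self):
        eff = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)],
            "emotion": ["fearful"] * 8,
            "effect": -np.arange(8.0),
            "trait_anxiety": 20 + 5 * np.arange(8.0),
        })
        r, p, bf = anxiety_effect_correlation(eff, "fearful")
        assert r == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([30, 35, 40, 50, 60.0])
        y = np.array([0.2, 0.1, 0.0, -0.2, -0.25])
        eff = pd.DataFrame({"subject_id": list("abcde"),
                            "emotion": ["fearful"] * 5,
                            "effect": y, "trait_anxiety": x})
        r, p, bf = anxiety_effect_correlation(eff, "fearful")
        hand = (np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1)))
        assert r == pytest.approx(hand)
        assert 0 < p < 1 and bf > 0

    def test_subject_effects_are_unexpected_minus_expected(self):
        df = pd.DataFrame(
            _mk("s1", [1.0] * 4, emotion="neutral", expectation="expected")
            + _mk("s1", [1.5] * 4, emotion="neutral", expectation="unexpected")
        )
        df["experiment_id"] = 1
        df["trait_anxiety"] = 40.0
        eff = subject_expectation_effects(df)
        row = eff[(eff.subject_id == "s1") & (eff.emotion == "neutral")]
        assert row["effect"].iloc[0] > 0
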