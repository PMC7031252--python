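"""Mixed-effects suite: estimation correctness, robust SEs, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import predinfer as pi
from predinfer.regression import _fit, white_test


def _toy_panel(n_subj=40, n_trial=60, seed=0, noise=0.0, slope=-3.0):
    """Exact (or nearly exact) linear panel: action = 10 - slope-modulated z_conf."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        z = rng.standard_normal(n_trial)
        z = (z - z.mean()) / z.std(ddof=1)
        y = 10.0 + slope * z + (rng.standard_normal(n_trial) * noise if noise else 0.0)
        rows.append(pd.DataFrame({
            "subject": s, "z_conf_next": z, "action": y,
            "age_z": rng.standard_normal() * np.ones(n_trial),
            "gender": float(s % 2) * np.ones(n_trial),
            "iq_z": rng.standard_normal() * np.ones(n_trial),
        }))
    return pd.concat(rows, ignore_index=True)


class TestCouplingModel:
    def test_exact_linear_data_recovers_slope(self):
        data = _toy_panel(noise=0.0, slope=-3.0)
        res = pi.fit_coupling_model(data)
        assert res.coef("z_conf_next") == pytest.approx(-3.0, abs=1e-6)
        assert res.coef("Intercept") == pytest.approx(10.0, abs=1e-6)

    def test_known_negative_coupling_in_cohort(self, analysis_table):
        res = pi.fit_coupling_model(analysis_table, moderators=("AD", "CIT", "SW"), m_bonf=3)
        assert res.coef("z_conf_next") < 0
        assert res.n_subjects == 30
        assert {"estimate", "robust_se", "p_bonf"} <= set(res.table.columns)

    def test_row_shuffling_invariant(self, analysis_table):
        res1 = pi.fit_coupling_model(analysis_table)
        shuffled = analysis_table.sample(frac=1.0, random_state=5)
        res2 = pi.fit_coupling_model(shuffled)
        assert res1.coef("z_conf_next") == pytest.approx(res2.coef("z_conf_next"), rel=1e-6)


class TestLevelModel:
    def test_null_data_intercept_is_grand_mean(self):
        rng = np.random.default_rng(3)
        n_subj, n_trial = 30, 40
        data = pd.DataFrame({
            "subject": np.repeat(np.arange(n_subj), n_trial),
            "conf_next": 50.0 + np.repeat(rng.standard_normal(n_subj), n_trial)
            + rng.standard_normal(n_subj * n_trial),
            "age_z": np.repeat(rng.standard_normal(n_subj), n_trial),
            "gender": np.repeat(rng.binomial(1, 0.5, n_subj).astype(float), n_trial),
            "iq_z": np.repeat(rng.standard_normal(n_subj), n_trial),
        })
        for c in ("age_z", "gender", "iq_z"):  # centered: intercept = grand mean
            data[c] -= data[c].mean()
        res = pi.fit_level_model(data, dv="confidence")
        assert res.coef("Intercept") == pytest.approx(data["conf_next"].mean(), abs=0.3)

    def test_moderator_effects_recovered(self):
        """Injected CIT -> +6 confidence units and AD -> -4 are recovered
        within 2 robust SEs (clip-free configuration)."""
        defaults = pi.AgentParams(conf_intercept=50.0, w_hit=4.0)
        effects = {"CIT": {"conf_intercept": 6.0}, "AD": {"conf_intercept": -4.0}, "SW": {}}
        trials, subjects = pi.simulate_cohort(n_subjects=80, effects=effects,
                                              defaults=defaults, seed=41)
        d = pi.apply_trial_exclusions(pi.derive_trials(trials))
        tab = pi.prepare_analysis_table(d, subjects, moderators=("AD", "CIT", "SW"))
        res = pi.fit_level_model(tab, dv="confidence", moderators=("AD", "CIT", "SW"), m_bonf=3)
        t = res.table.set_index("term")
        for term, truth in [("CIT_z", 6.0), ("AD_z", -4.0)]:
            assert abs(t.loc[term, "estimate"] - truth) < 2 * t.loc[term, "robust_se"]

    def test_bad_dv_rejected(self, analysis_table):
        with pytest.raises(ValueError):
            pi.fit_level_model(analysis_table, dv="points")


class TestEvidenceModel:
    def test_evidence_signs_on_cohort(self, analysis_table):
        res = pi.fit_evidence_model(analysis_table, dv="confidence")
        # generated confidence falls with surprise/uncertainty, rises after hits
        assert res.coef("z_cpp") < 0
        assert res.coef("z_ru") < 0
        assert res.coef("hit01") > 0
        assert res.coef("z_abs_peb") < 0

    def test_action_evidence_learning_structure(self, analysis_table):
        res = pi.fit_evidence_model(analysis_table, dv="action")
        # update magnitude grows with |PEb| weighted by CPP and RU (alpha = CPP + RU)
        assert res.coef("abs_peb:CPP") > 0
        assert res.coef("abs_peb:RU") > 0

    def test_rank_deficiency_informative(self, analysis_table):
        broken = analysis_table.copy()
        broken["hit01"] = 1.0  # constant Hit regressor
        with pytest.raises(ValueError, match="rank deficient"):
            pi.fit_evidence_model(broken, dv="confidence")


class TestRobustSE:
    def test_homoskedastic_ratio_near_one(self):
        # homoskedastic residuals with genuine random intercepts and slopes:
        # model-based and clustered sandwich SEs agree
        rng = np.random.default_rng(8)
        n_subj, n_trial = 60, 80
        rows = []
        for s in range(n_subj):
            x = rng.standard_normal(n_trial)
            y = (10 + rng.standard_normal()
                 + (-3.0 + 0.5 * rng.standard_normal()) * x
                 + rng.standard_normal(n_trial) * 2.0)
            rows.append(pd.DataFrame({"subject": s, "y": y, "x": x}))
        data = pd.concat(rows, ignore_index=True)
        res = _fit("y ~ x", data, re_formula="~x", model_id="hom")
        t = res.table.set_index("term")
        ratio = t.loc["x", "robust_se"] / t.loc["x", "se"]
        assert 0.9 < ratio < 1.1

    def test_heteroskedastic_divergence(self):
        # residual SD proportional to |x|: sandwich inflates the slope SE
        rng = np.random.default_rng(9)
        n_subj, n_trial = 50, 80
        rows = []
        for s in range(n_subj):
            x = rng.standard_normal(n_trial)
            y = 2.0 + 1.5 * x + rng.standard_normal(n_trial) * (0.2 + 2.0 * np.abs(x))
            rows.append(pd.DataFrame({"subject": s, "y": y, "x": x}))
        data = pd.concat(rows, ignore_index=True)
        res = _fit("y ~ x", data, re_formula="1", model_id="het")
        t = res.table.set_index("term")
        assert t.loc["x", "robust_se"] > 1.3 * t.loc["x", "se"]

    def test_single_cluster_degenerate(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame({"subject": 0, "x": rng.standard_normal(50)})
        data["y"] = 1.0 + data["x"] + rng.standard_normal(50)
        with pytest.warns(UserWarning, match="cluster"):
            res = _fit("y ~ x", data, re_formula="1", model_id="one")
        assert res.table["robust_se"].isna().all()


class TestWhiteTest:
    def test_constant_residuals_zero_statistic(self):
        stat, p = white_test(np.ones(100), np.column_stack([np.ones(100), np.arange(100.0)]))
        assert stat == 0.0 and p == 1.0

    def test_calibrated_under_homoskedasticity(self):
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(200):
            x = rng.standard_normal(150)
            resid = rng.standard_normal(150)
            _, p = white_test(resid, x)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform").pvalue
        assert ks > 0.01

    def test_detects_variance_structure(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(50):
            x = rng.standard_normal(300)
            resid = rng.standard_normal(300) * (0.2 + np.abs(x))
            _, p = white_test(resid, x)
            rejections += p < 0.05
        assert rejections / 50 > 0.5


class TestCorrections:
    def test_bonferroni_cases(self):
        assert pi.bonferroni(0.01, 9) == pytest.approx(0.09)
        assert pi.bonferroni(0.2, 9) == 1.0
        assert pi.bonferroni(0.04, 1) == pytest.approx(0.04)
        with pytest.raises(ValueError):
            pi.bonferroni(0.05, 0)

    def test_percent_change(self):
        assert pi.percent_change_effect(1.30, -8.85) == pytest.approx(14.7, abs=0.05)
        assert pi.percent_change_effect(0.0, -8.85) == 0.0
        with pytest.warns(UserWarning):
            assert np.isnan(pi.percent_change_effect(1.0, 0.0))

    def test_positive_interaction_on_negative_main_is_attenuation(self):
        pct = pi.percent_change_effect(2.0, -10.0)
        assert pct > 0  # shrinks the magnitude of a negative effect


def test_results_csv_roundtrip(tmp_path, analysis_table):
    res = pi.fit_level_model(analysis_table, dv="confidence", moderators=("CIT",), m_bonf=9)
    out = tmp_path / "results.csv"
    pi.regression.results_to_csv(res, out)
    back = pd.read_csv(out)
    assert "model_id" in back.columns
    assert len(back) == len(res.table)


def test_single_moderator_same_in_both_regimes(analysis_table):
    """With one moderator, the separate-questionnaire and joint-dimension
    calls are the same model up to the Bonferroni m."""
    a = pi.fit_level_model(analysis_table, dv="confidence", moderators=("CIT",), m_bonf=9)
    b = pi.fit_level_model(analysis_table, dv="confidence", moderators=("CIT",), m_bonf=1)
    assert a.coef("CIT_z") == pytest.approx(b.coef("CIT_z"))
    pa = a.pvalue("CIT_z", adjusted=True)
    pb = b.pvalue("CIT_z", adjusted=True)
    assert pa == pytest.approx(min(1.0, 9 * a.pvalue("CIT_z")))
    assert pb == pytest.approx(a.pvalue("CIT_z"))
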