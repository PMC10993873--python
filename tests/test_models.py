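"""Statistical layer: AICc, mixed models, beta regression, model ranking."""

import numpy as np
import pandas as pd
import pytest

from strokefate.cohort import CohortEffectSpec, make_cohort
from strokefate.models import (
    PERFUSION_CONFIGS,
    aicc,
    aicc_from_aic,
    correlate_hyperacute,
    fit_fraction_glmm,
    fit_perfusion_lmm,
    multimodel_inference,
)


@pytest.fixture(scope="module")
def cohort():
    return make_cohort(CohortEffectSpec(seed=21))


class TestAicc:
    def test_closed_form_example(self):
        assert aicc_from_aic(100.0, 5, 40) == pytest.approx(
            100.0 + 60.0 / 34.0, abs=1e-12
        )

    def test_converges_to_aic_for_large_n(self):
        assert abs(aicc_from_aic(100.0, 5, 10**4) - 100.0) < 0.01

    def test_matches_loglik_form(self):
        llf, k, n = -45.0, 4, 30
        assert aicc(llf, k, n) == pytest.approx(
            aicc_from_aic(2 * k - 2 * llf, k, n)
        )

    def test_degenerate_sample_size_is_infinite(self):
        assert aicc_from_aic(100.0, 10, 11) == np.inf


class TestPerfusionLmm:
    def test_effect_table_terms(self, cohort):
        res = fit_perfusion_lmm(cohort.rr, "cbf")
        assert set(res["effects"]["term"]) == {"timepoint", "occlusion", "sex"}
        assert (res["effects"]["df1"] == [2, 1, 1]).all()
        assert not res["downgraded"]
        # strong planted session effect is detected
        p_time = res["effects"].set_index("term").loc["timepoint", "p"]
        assert p_time < 1e-6

    def test_duplication_leaves_point_estimates_unchanged(self, cohort):
        res1 = fit_perfusion_lmm(cohort.rr, "cbv")
        doubled = pd.concat(
            [cohort.rr, cohort.rr.assign(subject=cohort.rr.subject + "_b")],
            ignore_index=True,
        )
        res2 = fit_perfusion_lmm(doubled, "cbv")
        fe1 = np.asarray(res1["fit"].fe_params)
        fe2 = np.asarray(res2["fit"].fe_params)
        assert np.allclose(fe1, fe2, rtol=1e-6)

    def test_posthoc_bonferroni_bounded(self, cohort):
        res = fit_perfusion_lmm(cohort.rr, "mtt")
        assert (res["posthoc"]["p_bonferroni"] <= 1.0).all()
        assert len(res["posthoc"]) == 3

    def test_missing_index_rejected(self, cohort):
        with pytest.raises(ValueError):
            fit_perfusion_lmm(cohort.rr, "adc")


class TestFractionGlmm:
    def test_fitted_means_in_unit_interval(self, cohort):
        res = fit_fraction_glmm(cohort.fractions, "f_hypo")
        assert np.all(res["fitted_means"] > 0)
        assert np.all(res["fitted_means"] < 1)

    def test_out_of_range_fractions_rejected(self, cohort):
        bad = cohort.fractions.copy()
        bad.loc[bad.index[0], "f_hypo"] = 1.5
        with pytest.raises(ValueError):
            fit_fraction_glmm(bad, "f_hypo")

    def test_all_boundary_rejected(self, cohort):
        bad = cohort.fractions.copy()
        bad["f_hypo"] = 0.0
        with pytest.raises(ValueError, match="boundary"):
            fit_fraction_glmm(bad, "f_hypo")

    def test_recovers_planted_ipsi_contra_sign(self, cohort):
        sub = cohort.fractions.query(
            "roi == 'delayed' and timepoint == 'post_0.5h'"
        )
        res = fit_fraction_glmm(sub, "f_hypo", "C(hemisphere)")
        coef = res["params"]["C(hemisphere)[T.ipsilateral]"]
        assert coef > 0  # planted ipsilateral hypoperfusion excess
        assert res["pvalues"]["C(hemisphere)[T.ipsilateral]"] < 0.01


class TestMultimodel:
    def test_config_lattice_excludes_mtt_with_flow_terms(self):
        for cfg in PERFUSION_CONFIGS:
            assert not ("rrMTT" in cfg and ({"rrCBF", "rrCBV"} & set(cfg)))

    def test_ranking_sorted_and_base_delta_zero(self, cohort):
        r = multimodel_inference(cohort.modeling_table(), "volume_change")
        aiccs = r.table["aicc"].to_numpy()
        assert np.all(np.diff(aiccs) >= 0)
        base_delta = r.table.set_index("model").loc["base", "delta_aicc_vs_base"]
        assert base_delta == 0.0
        assert set(r.table["model"]) == {
            "rrCBF & rrCBV", "rrMTT", "base", "rrCBV", "rrCBF", "NULL"
        }

    def test_deterministic(self, cohort):
        t1 = multimodel_inference(cohort.modeling_table(), "volume_change").table
        t2 = multimodel_inference(cohort.modeling_table(), "volume_change").table
        pd.testing.assert_frame_equal(t1, t2)

    def test_ranking_invariant_to_predictor_scaling(self, cohort):
        wide = cohort.modeling_table()
        r1 = multimodel_inference(wide, "volume_change")
        scaled = wide.copy()
        scaled["rrCBF"] = scaled["rrCBF"] * 10 + 7.0
        r2 = multimodel_inference(scaled, "volume_change")
        assert list(r1.table["model"]) == list(r2.table["model"])
        assert np.allclose(r1.table["aicc"], r2.table["aicc"])

    def test_poisson_branch_reports_nagelkerke(self, cohort):
        r = multimodel_inference(cohort.modeling_table(), "sds")
        assert r.family == "poisson"
        assert (r.table["r2_nagelkerke"].dropna() <= 1.0).all()
        null_r2 = r.table.set_index("model").loc["NULL", "r2_nagelkerke"]
        assert null_r2 == pytest.approx(0.0, abs=1e-10)

    def test_unknown_outcome_rejected(self, cohort):
        with pytest.raises(ValueError):
            multimodel_inference(cohort.modeling_table(), "histology")


class TestCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        out = correlate_hyperacute(x, x)
        assert out["r"] == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            correlate_hyperacute(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            correlate_hyperacute(np.arange(2.0), np.arange(2.0))

    def test_null_sampling_distribution(self):
        rng = np.random.default_rng(31)
        rs = []
        for _ in range(1000):
            x, y = rng.standard_normal((2, 40))
            rs.append(correlate_hyperacute(x, y)["r"])
        rs = np.abs(rs)
        assert np.mean(rs < 0.32) > 0.92  # ~95% of |r| under the null bound

    def test_power_for_planted_r(self):
        """r = 0.4 at n = 40 is detected in roughly 72% of replicates."""
        rng = np.random.default_rng(32)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.standard_normal(40)
            y = 0.4 * x + np.sqrt(1 - 0.16) * rng.standard_normal(40)
            hits += correlate_hyperacute(x, y)["p"] < 0.05
        assert hits / n_rep == pytest.approx(0.72, abs=0.08)

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(33)
        x, y = rng.standard_normal((2, 30))
        out = correlate_hyperacute(x, y, n_comparisons=6)
        assert out["p_adjusted"] == pytest.approx(min(out["p"] * 6, 1.0))
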