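"""Firing-rate correlations with saliency, luminance, and trait ratings."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_unit_event_data
from fixsel import associations as assoc
from fixsel.core import AnalysisConfig
from fixsel.selectivity import classify_units_fixation, cohort_event_data
from fixsel.stats import spawn_rng


class TestFixationValueCorrelation:
    def test_values_equal_rates_r_one(self):
        rng = spawn_rng(0, 30)
        rates = rng.uniform(1, 5, 50)
        d = make_unit_event_data(rates, ["eyes"] * 50)
        rec = assoc.fixation_value_correlation(d, rates, "saliency", "eyes")
        assert rec.pearson_r == pytest.approx(1.0)

    def test_planted_linear_coupling_recovered(self):
        rng = spawn_rng(1, 30)
        n, rho = 500, 0.3
        z = rng.normal(size=n)
        rates = 3.0 + z
        values = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        d = make_unit_event_data(rates, ["eyes"] * n)
        rec = assoc.fixation_value_correlation(d, values, "saliency", "eyes")
        assert rec.pearson_r == pytest.approx(rho, abs=0.1)

    def test_constant_values_flagged(self):
        d = make_unit_event_data(np.arange(20.0), ["eyes"] * 20)
        rec = assoc.fixation_value_correlation(d, np.ones(20), "saliency", "eyes")
        assert rec.flagged and rec.pearson_r is None

    def test_too_few_fixations_flagged(self):
        d = make_unit_event_data([1.0, 2, 3], ["eyes"] * 3)
        rec = assoc.fixation_value_correlation(d, np.arange(3.0), "v", "eyes")
        assert rec.flagged

    def test_affine_invariance_of_r(self):
        rng = spawn_rng(2, 30)
        rates = rng.uniform(0, 4, 60)
        vals = rng.normal(size=60)
        d = make_unit_event_data(rates, ["mouth"] * 60)
        r1 = assoc.fixation_value_correlation(d, vals, "v", "mouth").pearson_r
        r2 = assoc.fixation_value_correlation(d, 5 - 3 * vals, "v", "mouth").pearson_r
        assert r2 == pytest.approx(-r1)

    def test_scope_restriction(self):
        rng = spawn_rng(3, 30)
        rois = ["eyes"] * 30 + ["nose"] * 30
        rates = np.concatenate([np.arange(30.0), rng.uniform(0, 1, 30)])
        vals = np.concatenate([np.arange(30.0), rng.uniform(0, 1, 30)])
        d = make_unit_event_data(rates, rois)
        within = assoc.fixation_value_correlation(d, vals, "v", "eyes")
        assert within.n_fixations == 30
        assert within.pearson_r == pytest.approx(1.0)


class TestGroupTests:
    def test_symmetric_records_not_significant(self):
        recs, flags = [], {}
        for i, r in enumerate(np.linspace(-0.2, 0.2, 21)):
            recs.append(assoc.CorrelationRecord(f"u{i}", "v", "eyes", float(r),
                                                0.5, 50))
            flags[f"u{i}"] = i % 2 == 0
        out = assoc.group_correlation_test(recs, flags)
        assert abs(out["selective_vs_zero"].statistic) < 1.2
        assert not out["selective_vs_zero_significant"]

    def test_bonferroni_family_threshold(self):
        # raw p = 0.004 survives alpha=0.05 unadjusted but not m=16
        recs, flags = [], {}
        rng = spawn_rng(4, 31)
        for i in range(20):
            recs.append(assoc.CorrelationRecord(f"u{i}", "v", "eyes",
                                                float(0.1 + 0.1 * rng.normal()),
                                                0.01, 50))
            flags[f"u{i}"] = True
        out = assoc.group_correlation_test(recs, flags, bonferroni_m=16)
        assert out["bonferroni_threshold"] == pytest.approx(0.05 / 16)
        assert 0.004 > out["bonferroni_threshold"]

    def test_planted_saliency_scoping_pattern(self, planted_cohort, ana_cfg):
        # coupling planted only inside eyes/mouth: within-scope significant
        # for selective units, outside-scope and non-selective not
        sessions = [s for s, _ in planted_cohort]
        classes = [classify_units_fixation(s, ana_cfg) for s in sessions]
        data = cohort_event_data(sessions, classes, ana_cfg)
        sess_of = {u.unit_id: s for s in sessions for u in s.units}
        flags = {u: (c.label != "none") for m in classes for u, c in m.items()}
        results = {}
        for scope in ("within_preferred", "outside_preferred"):
            recs = [assoc.fixation_value_correlation(
                d, assoc.saliency_values_for(d, sess_of[d.unit_id]),
                "saliency", scope) for d in data]
            results[scope] = assoc.group_correlation_test(recs, flags)
        within, outside = results["within_preferred"], results["outside_preferred"]
        assert within["selective_vs_zero"].statistic > 0
        assert within["selective_vs_zero"].p_value < 0.01
        assert outside["selective_vs_zero"].p_value > 0.05
        assert abs(within["nonselective_vs_zero"].statistic) < 2.5

    def test_planted_trait_effect_pattern(self, planted_cohort, ana_cfg):
        # the planted 'warm' coupling shows in selective units on eye fixations
        sessions = [s for s, _ in planted_cohort]
        classes = [classify_units_fixation(s, ana_cfg) for s in sessions]
        data = cohort_event_data(sessions, classes, ana_cfg)
        sess_of = {u.unit_id: s for s in sessions for u in s.units}
        flags = {u: (c.label != "none") for m in classes for u, c in m.items()}
        recs = [assoc.fixation_value_correlation(
            d, assoc.trait_values_for(d, sess_of[d.unit_id], "warm"),
            "trait_warm", "eyes") for d in data]
        out = assoc.group_correlation_test(recs, flags)
        assert out["selective_vs_zero"].p_value < 0.05
        assert out["selective_vs_nonselective"].p_value < 0.05


class TestLuminance:
    def test_luminance_uncorrelated_with_planted_modulation(self, planted_cohort,
                                                            ana_cfg):
        sessions = [s for s, _ in planted_cohort]
        classes = [classify_units_fixation(s, ana_cfg) for s in sessions]
        data = [d for d in cohort_event_data(sessions, classes, ana_cfg)
                if d.label != "none"]
        sess_of = {u.unit_id: s for s in sessions for u in s.units}
        out = assoc.luminance_control(data, sess_of)
        for scope in ("eyes", "mouth"):
            res = out[scope]["group_test"]
            assert res is not None and res.p_value > 0.01

    def test_luminance_as_rate_sanity(self, small_session):
        session, _ = small_session
        cfg = AnalysisConfig()
        classes = classify_units_fixation(session, cfg)
        d = cohort_event_data([session], [classes], cfg)[0]
        lum = assoc.luminance_values_for(d, session)
        d.rates = lum.copy()
        rec = assoc.fixation_value_correlation(d, lum, "luminance", "eyes")
        assert rec.pearson_r == pytest.approx(1.0)

    def test_eye_roi_darker_by_construction(self, small_session):
        faces = small_session[0].faces
        assert (faces["lum_eyes"].mean() < faces["lum_mouth"].mean())


class TestTraitReduce:
    def test_two_raters_mean(self):
        df = pd.DataFrame({"face_id": ["f0", "f0"], "rater_id": ["a", "b"],
                           "rating": [3.0, 5.0]})
        assert assoc.trait_rating_reduce(df).loc["f0"] == 4.0

    def test_single_rater_identity(self):
        df = pd.DataFrame({"face_id": ["f0"], "rater_id": ["a"], "rating": [6.0]})
        assert assoc.trait_rating_reduce(df).loc["f0"] == 6.0

    def test_modes_agree_when_raters_identical(self):
        df = pd.DataFrame({"face_id": ["f0", "f0"], "rater_id": ["a", "b"],
                           "rating": [2.0, 2.0]})
        consensus = assoc.trait_rating_reduce(df, "consensus").loc["f0"]
        per_rater = assoc.trait_rating_reduce(df, "per_rater")
        assert (per_rater == consensus).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assoc.trait_rating_reduce(pd.DataFrame(columns=["face_id", "rater_id",
                                                            "rating"]))
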