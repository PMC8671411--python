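"""Unit classification, FSI/SSI, permutation nulls, PSTH, ROC, overlap."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_unit_event_data
from fixsel.core import AnalysisConfig
from fixsel.selectivity import (EYES_PREFERRING, MOUTH_PREFERRING, NONE_CLASS,
                                UnitClass, classify_unit,
                                classify_units_fixation,
                                classify_units_saccade, cohort_event_data,
                                compute_fsi, event_window, fsi_cdf_compare,
                                oneback_fsi, overlap_analysis,
                                permutation_mean_fsi, pooled_fsi,
                                prevalence_test, psth, roc_auc_counts,
                                serial_order_fsi,
                                unit_event_data_with_spikes)
from fixsel.stats import spawn_rng


class TestEventWindow:
    def test_fixation_window_pads_both_sides(self, ana_cfg):
        ev = {"event_type": "fixation", "t_start": 1.0, "t_end": 1.6}
        assert event_window(ev, ana_cfg) == (0.8, 1.8)

    def test_saccade_window_anchored_at_onset(self, ana_cfg):
        ev = {"event_type": "saccade", "t_start": 2.0, "t_end": 2.05}
        assert event_window(ev, ana_cfg) == (1.8, 2.2)


class TestClassification:
    def test_planted_units_recovered(self, default_session, ana_cfg):
        session, truth = default_session
        classes = classify_units_fixation(session, ana_cfg)
        planted = {u: k for u, k in truth.unit_class.items() if k != "none"}
        hits = sum(classes[u].label == k for u, k in planted.items())
        assert hits / len(planted) >= 0.9

    def test_label_follows_sign_of_difference(self, default_session, ana_cfg):
        session, truth = default_session
        classes = classify_units_fixation(session, ana_cfg)
        for u, c in classes.items():
            if c.label == EYES_PREFERRING:
                assert c.t_stat > 0
            elif c.label == MOUTH_PREFERRING:
                assert c.t_stat < 0

    def test_identical_rates_not_selected(self):
        data = make_unit_event_data([2.0, 2.0, 2.0, 2.0],
                                    ["eyes", "eyes", "mouth", "mouth"])
        c = classify_unit(data, AnalysisConfig())
        assert c.label == NONE_CLASS
        assert c.p_value == 1.0

    def test_too_few_events_unclassifiable(self):
        data = make_unit_event_data([2.0, 3.0, 1.0], ["eyes", "eyes", "mouth"])
        c = classify_unit(data, AnalysisConfig())
        assert c.label == NONE_CLASS
        assert np.isnan(c.p_value)

    def test_saccade_classification_recovers_planted(self, default_session, ana_cfg):
        # gain starts at preceding saccade onset, so the 400 ms saccade window
        # carries the class signal too
        session, truth = default_session
        classes = classify_units_saccade(session, ana_cfg)
        planted = {u: k for u, k in truth.unit_class.items() if k != "none"}
        hits = sum(classes[u].label == k for u, k in planted.items())
        assert hits / len(planted) >= 0.5

    def test_window_robustness_agreement(self, default_session, ana_cfg):
        # classification with the pre-onset padding removed agrees >= 90%
        session, _ = default_session
        default = classify_units_fixation(session, ana_cfg)
        no_pre = classify_units_fixation(
            session, AnalysisConfig(fixation_window_pre=0.0))
        agree = np.mean([default[u].label == no_pre[u].label for u in default])
        assert agree >= 0.9


class TestPrevalence:
    def test_zero_selected_gives_one(self):
        assert prevalence_test(0, 100, 0.05) == 1.0

    def test_matches_pmf_summation(self):
        from scipy import stats as sps
        brute = float(sps.binom.pmf(np.arange(5, 101), 100, 0.05).sum())
        assert prevalence_test(5, 100, 0.05) == pytest.approx(brute, rel=1e-9)


class TestFsi:
    def test_eyes_preferring_worked_example(self):
        # FR_i = 6 on the eyes, mouth mean 2, baseline 4 -> +100%
        data = make_unit_event_data([6.0, 2.0], ["eyes", "mouth"],
                                    baseline=4.0, label=EYES_PREFERRING)
        fsi = compute_fsi(data)
        assert fsi.loc[fsi["roi"] == "eyes", "fsi_percent"].iloc[0] == 100.0

    def test_mouth_preferring_sign_flip(self):
        # FR_i = 1 on an eye fixation, mouth mean 3, baseline 4 -> +50%
        data = make_unit_event_data([1.0, 3.0], ["eyes", "mouth"],
                                    baseline=4.0, label=MOUTH_PREFERRING)
        fsi = compute_fsi(data)
        assert fsi.loc[fsi["roi"] == "eyes", "fsi_percent"].iloc[0] == 50.0

    def test_mouth_mean_exactly_zero_for_every_unit(self, default_session, ana_cfg):
        session, _ = default_session
        classes = classify_units_fixation(session, ana_cfg)
        data = cohort_event_data([session], [classes], ana_cfg)
        for d in data:
            rec = compute_fsi(d)
            mouth = rec.loc[rec["roi"] == "mouth", "fsi_percent"]
            assert abs(mouth.mean()) < 1e-9

    def test_fsi_covers_all_rois(self):
        data = make_unit_event_data([1.0, 2, 3, 4],
                                    ["eyes", "mouth", "nose", "other"])
        assert set(compute_fsi(data)["roi"]) == {"eyes", "mouth", "nose", "other"}

    def test_zero_baseline_excluded(self):
        data = make_unit_event_data([1.0, 2.0], ["eyes", "mouth"], baseline=0.0)
        with pytest.raises(ValueError, match="baseline"):
            compute_fsi(data)


class TestCdfAndPermutation:
    def test_identical_samples_ks_zero(self):
        rec = pd.DataFrame({"roi": ["eyes"] * 5 + ["mouth"] * 5,
                            "fsi_percent": list(range(5)) * 2})
        out = fsi_cdf_compare(rec)
        assert out["test"].statistic == 0.0
        assert out["test"].p_value == 1.0

    def test_planted_shift_detected(self, default_session, ana_cfg):
        session, _ = default_session
        classes = classify_units_fixation(session, ana_cfg)
        data = cohort_event_data([session], [classes], ana_cfg)
        selective = [d for d in data if d.label != NONE_CLASS]
        rec = pooled_fsi(selective)
        out = fsi_cdf_compare(rec)
        assert out["test"].statistic > 0
        assert out["test"].p_value < 1e-3
        # eye-fixation FSI above zero on average for selective units
        assert rec.loc[rec["roi"] == "eyes", "fsi_percent"].mean() > 0

    def test_permutation_planted_significant(self, default_session):
        session, _ = default_session
        cfg = AnalysisConfig(n_permutations=499)
        classes = classify_units_fixation(session, cfg)
        data = cohort_event_data([session], [classes], cfg)
        selective = [d for d in data if d.label != NONE_CLASS]
        out = permutation_mean_fsi(selective, cfg, seed=1)
        assert out["p_value"] <= 0.01
        assert out["observed"] > np.mean(out["null"])

    def test_permutation_reproducible(self):
        rng = spawn_rng(2, 5)
        data = [make_unit_event_data(rng.poisson(3, 40) + 0.0,
                                     ["eyes", "mouth"] * 20)]
        cfg = AnalysisConfig(n_permutations=200)
        a = permutation_mean_fsi(data, cfg, seed=3)
        b = permutation_mean_fsi(data, cfg, seed=3)
        np.testing.assert_array_equal(a["null"], b["null"])
        assert a["p_value"] == b["p_value"]

    def test_serial_order_groups_and_late_only_effect(self):
        rng = spawn_rng(4, 5)
        # effect only in serial orders 3-4: group {1} null, group {3,4} hot
        def unit(i):
            orders = [1, 1, 2, 2, 3, 3, 4, 4] * 8
            rois = ["eyes", "mouth"] * 32
            rates = np.array([rng.poisson(30) + 0.0 for _ in orders])
            late_eye = [(o >= 3 and r == "eyes") for o, r in zip(orders, rois)]
            rates[np.array(late_eye)] += 25
            return make_unit_event_data(rates, rois, serial_order=orders,
                                        unit_id=f"u{i}")
        data = [unit(i) for i in range(6)]
        cfg = AnalysisConfig(n_permutations=199)
        out = serial_order_fsi(data, cfg, seed=5)
        assert out["3+4"]["p_value"] < 0.05
        assert out["1"]["p_value"] > 0.05

    def test_oneback_subset_partition(self, planted_cohort, ana_cfg):
        sessions = [s for s, _ in planted_cohort]
        classes = [classify_units_fixation(s, ana_cfg) for s in sessions]
        data = cohort_event_data(sessions, classes, ana_cfg)
        selective = [d for d in data if d.label != NONE_CLASS]
        rec = pooled_fsi(selective)
        n_repeat = int(rec["is_one_back"].sum())
        assert 0 < n_repeat < len(rec)
        # ~9% of 500 trials are repeats, so roughly a tenth of the records
        assert n_repeat / len(rec) == pytest.approx(0.09, abs=0.03)
        out = oneback_fsi(rec)
        # planted effect does not depend on novelty: still detected
        assert out["test"].p_value < 0.001


class TestPsth:
    def test_identical_conditions_no_significant_bins(self, default_session, ana_cfg):
        session, _ = default_session
        data = [unit_event_data_with_spikes(u, session, ana_cfg)
                for u in session.units[:6]]
        res = psth(data, ana_cfg, conditions=("nose", "nose"))
        assert not res.significant.any()

    def test_bonferroni_threshold_arithmetic(self, default_session, ana_cfg):
        session, _ = default_session
        data = [unit_event_data_with_spikes(u, session, ana_cfg)
                for u in session.units[:4]]
        res = psth(data, ana_cfg, span=(-0.5, 0.5))
        n_bins = res.bin_centers.size
        assert n_bins == 20
        np.testing.assert_array_equal(res.significant,
                                      res.p_values < 0.05 / 20)

    def test_planted_gain_significant_before_fixation_onset(self, planted_cohort,
                                                            ana_cfg):
        sessions = [s for s, _ in planted_cohort]
        truths = [t for _, t in planted_cohort]
        data = []
        for s, t in zip(sessions, truths):
            for u in s.units:
                if t.unit_class[u.unit_id] == "eyes_preferring":
                    data.append(unit_event_data_with_spikes(
                        u, s, ana_cfg, label=EYES_PREFERRING))
        res = psth(data, ana_cfg)
        sig_centers = res.bin_centers[res.significant]
        assert sig_centers.size > 0
        # gain switches on at the preceding saccade's onset
        assert sig_centers.min() < 0


class TestRoc:
    def test_perfect_separation(self):
        assert roc_auc_counts([0, 1, 0, 1], [10, 11, 10, 11]) == 1.0

    def test_identical_distributions(self):
        assert roc_auc_counts([3, 3, 3], [3, 3, 3]) == 0.5

    def _exhaustive_auc(self, a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        pos, neg = (a, b) if a.mean() >= b.mean() else (b, a)
        thr = np.concatenate([np.unique(np.concatenate([pos, neg])),
                              [max(pos.max(), neg.max()) + 1]])
        tpr = np.array([(pos >= t).mean() for t in thr])[::-1]
        fpr = np.array([(neg >= t).mean() for t in thr])[::-1]
        auc = float(np.trapezoid(tpr, fpr))
        return max(auc, 1 - auc)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_thresholds_within_range_20(self, seed):
        rng = spawn_rng(seed, 9)
        a = rng.integers(0, 12, 40)
        b = rng.integers(3, 20, 35)
        assert roc_auc_counts(a, b) == pytest.approx(self._exhaustive_auc(a, b))

    @pytest.mark.parametrize("seed", range(6))
    def test_never_below_half(self, seed):
        rng = spawn_rng(seed, 10)
        a = rng.poisson(4, 30)
        b = rng.poisson(4.5, 25)
        assert roc_auc_counts(a, b) >= 0.5


class TestOverlap:
    def test_worked_example_counts(self):
        # 29 saccade-selective units of which 14 are also fixation-selective,
        # against 74/365 fixation-selective overall
        def unit(i, fix_sel, sacc_sel):
            mk = lambda sel: UnitClass(f"u{i}", EYES_PREFERRING if sel else
                                       NONE_CLASS, 1.0, 0.01 if sel else 0.5,
                                       10, 10)
            return mk(fix_sel), mk(sacc_sel)
        fix, sacc = {}, {}
        for i in range(365):
            fix_sel = i < 74
            sacc_sel = i < 14 or (74 <= i < 89)
            f, s = unit(i, fix_sel, sacc_sel)
            fix[f"u{i}"], sacc[f"u{i}"] = f, s
        out = overlap_analysis(fix, sacc)
        assert out["n_both"] == 14
        assert out["n_saccade_selective"] == 29
        assert out["test"].p_value == pytest.approx(4.92e-4, rel=0.05)

    def test_identical_proportions_p_one(self):
        fix, sacc = {}, {}
        for i in range(40):
            sel = i < 10
            fix[f"u{i}"] = UnitClass(f"u{i}", EYES_PREFERRING if sel else NONE_CLASS,
                                     1.0, 0.01 if sel else 0.6, 5, 5)
            sacc[f"u{i}"] = UnitClass(f"u{i}", EYES_PREFERRING, 1.0, 0.01, 5, 5)
        out = overlap_analysis(fix, sacc)
        # all units saccade-selective -> selective-subset proportion equals overall
        assert out["test"].p_value == pytest.approx(1.0)

    def test_mismatched_unit_sets_rejected(self):
        u = UnitClass("a", NONE_CLASS, 0.0, 0.5, 5, 5)
        with pytest.raises(ValueError):
            overlap_analysis({"a": u}, {"b": u})
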