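#!/usr/bin/env python
"""Eyes- vs mouth-preferring units: classification, indices, and controls.

On the simulated cohort this step (i) classifies every unit from fixation-
and saccade-aligned window rates, (ii) tests the prevalence of selective
units against the 5% chance rate and contrasts amygdala vs hippocampus,
(iii) computes per-fixation selectivity indices (FSI) and compares their
eyes/mouth distributions by KS test, with permutation, serial-order and
one-back controls, (iv) summarizes per-unit discriminability by ROC AUC,
and (v) tests the overlap of fixation- and saccade-selectivity.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from fixsel import selectivity as sel
from fixsel.core import AnalysisConfig, pooled_region, read_session
from fixsel.stats import chi2_2x2

ROOT = Path(__file__).resolve().parents[1]
SEED = 42


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    session_dirs = sorted(d for d in cohort_dir.iterdir() if d.is_dir()) \
        if cohort_dir.exists() else []
    if not session_dirs:
        raise SystemExit("no cohort found; run analysis/01_simulate_cohort.py first")
    sessions = [read_session(d) for d in session_dirs]
    truth = pd.concat([pd.read_csv(d / "ground_truth.tsv", sep="\t")
                       for d in session_dirs])
    cfg = AnalysisConfig()

    fix_classes = [sel.classify_units_fixation(s, cfg) for s in sessions]
    sacc_classes = [sel.classify_units_saccade(s, cfg) for s in sessions]
    all_fix = {u: c for m in fix_classes for u, c in m.items()}
    all_sacc = {u: c for m in sacc_classes for u, c in m.items()}

    unit_rows = []
    region_of = {u.unit_id: u.region for s in sessions for u in s.units}
    for u, c in all_fix.items():
        unit_rows.append({"unit_id": u, "region": region_of[u],
                          "fix_label": c.label, "fix_t": c.t_stat, "fix_p": c.p_value,
                          "sacc_label": all_sacc[u].label, "sacc_p": all_sacc[u].p_value})
    units_table = pd.DataFrame(unit_rows).merge(truth, on="unit_id")
    units_table.to_csv(ROOT / "results" / "03_unit_classes.tsv", sep="\t", index=False)

    n_total = len(all_fix)
    n_sel = sum(c.label != "none" for c in all_fix.values())
    n_sacc_sel = sum(c.label != "none" for c in all_sacc.values())
    planted = set(truth.loc[truth["true_class"] != "none", "unit_id"])
    recovered = sum(1 for u in planted if all_fix[u].label != "none")

    out = {
        "fixation_selective": f"{n_sel}/{n_total}",
        "fixation_prevalence_binomial_p": sel.prevalence_test(n_sel, n_total, cfg.alpha),
        "planted_recovered": f"{recovered}/{len(planted)}",
        "saccade_selective": f"{n_sacc_sel}/{n_total}",
    }

    by_region = {"amygdala": [0, 0], "hippocampus": [0, 0]}
    for u, c in all_fix.items():
        reg = pooled_region(region_of[u])
        by_region[reg][1] += 1
        if c.label != "none":
            by_region[reg][0] += 1
    (a_sel, a_tot), (h_sel, h_tot) = by_region["amygdala"], by_region["hippocampus"]
    if min(a_sel, h_sel) > 0:
        out["amygdala_vs_hippocampus_chi2_p"] = chi2_2x2(
            a_sel, a_tot - a_sel, h_sel, h_tot - h_sel).p_value
    out["by_region"] = {k: f"{v[0]}/{v[1]}" for k, v in by_region.items()}

    # FSI analyses on the selective sub-population
    data = sel.cohort_event_data(sessions, fix_classes, cfg)
    selective = [d for d in data if d.label != "none"]
    records = sel.pooled_fsi(selective)
    cdf = sel.fsi_cdf_compare(records)
    perm = sel.permutation_mean_fsi(selective, cfg, seed=SEED)
    orders = sel.serial_order_fsi(selective, cfg, seed=SEED)
    oneback = sel.oneback_fsi(records)
    out["fsi"] = {
        "eyes_vs_mouth_ks": {"KS": cdf["test"].statistic, "p": cdf["test"].p_value},
        "mean_fsi_eye_fixations_pct": float(
            records.loc[records["roi"] == "eyes", "fsi_percent"].mean()),
        "permutation_p": perm["p_value"],
        "serial_order_p": {k: (v["p_value"] if v else None) for k, v in orders.items()},
        "one_back_ks_p": oneback["test"].p_value,
    }

    # per-unit ROC AUC, eyes vs mouth windows
    aucs = {}
    for s in sessions:
        fix = s.fixations
        for u in s.units:
            aucs[u.unit_id] = sel.roc_auc(u, fix[fix["roi"] == "eyes"],
                                          fix[fix["roi"] == "mouth"], cfg)
    sel_auc = [aucs[u] for u, c in all_fix.items() if c.label != "none"]
    non_auc = [aucs[u] for u, c in all_fix.items() if c.label == "none"]
    out["roc_auc_mean"] = {"selective": float(np.mean(sel_auc)),
                           "nonselective": float(np.mean(non_auc))}

    overlap = sel.overlap_analysis(all_fix, all_sacc)
    out["overlap"] = {"both": overlap["n_both"],
                      "saccade_selective": overlap["n_saccade_selective"],
                      "chi2_p": overlap["test"].p_value}

    (ROOT / "results" / "03_selectivity.json").write_text(
        json.dumps(out, indent=2, default=float))
    print(json.dumps(out, indent=2, default=float))


if __name__ == "__main__":
    sys.exit(main())
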