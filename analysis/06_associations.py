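#!/usr/bin/env python
"""Firing-rate correlations with saliency, ROI luminance and trait ratings.

For each unit, correlates per-fixation window firing rates with (i) the DNN
saliency value under the fixation, within vs outside the preferred eyes and
mouth region, (ii) the viewed face's ROI luminance (a brightness-response
control expected null), and (iii) the face's consensus social-trait ratings
for eye fixations. Group tests contrast feature-selective vs non-selective
units; the trait family is Bonferroni-corrected (8 traits x 2 scopes).
"""

import json
import sys
from pathlib import Path

from fixsel import associations as assoc
from fixsel import selectivity as sel
from fixsel.core import TRAITS, AnalysisConfig, read_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    session_dirs = sorted(d for d in cohort_dir.iterdir() if d.is_dir()) \
        if cohort_dir.exists() else []
    if not session_dirs:
        raise SystemExit("no cohort found; run analysis/01_simulate_cohort.py first")
    sessions = [read_session(d) for d in session_dirs]
    cfg = AnalysisConfig()

    classes = [sel.classify_units_fixation(s, cfg) for s in sessions]
    data = sel.cohort_event_data(sessions, classes, cfg)
    sess_of = {u.unit_id: s for s in sessions for u in s.units}
    flags = {u: (c.label != "none") for m in classes for u, c in m.items()}

    def summarize(test):
        return None if test is None else {"t": round(test.statistic, 2),
                                          "p": float(test.p_value)}

    out = {"saliency": {}, "traits": {}, "luminance": {}}
    for scope in ("within_preferred", "outside_preferred"):
        recs = [assoc.fixation_value_correlation(
            d, assoc.saliency_values_for(d, sess_of[d.unit_id]), "saliency",
            scope) for d in data]
        g = assoc.group_correlation_test(recs, flags)
        out["saliency"][scope] = {
            "selective_vs_zero": summarize(g["selective_vs_zero"]),
            "nonselective_vs_zero": summarize(g["nonselective_vs_zero"]),
            "selective_vs_nonselective": summarize(g["selective_vs_nonselective"])}

    for trait in TRAITS:
        recs = [assoc.fixation_value_correlation(
            d, assoc.trait_values_for(d, sess_of[d.unit_id], trait),
            f"trait_{trait}", "eyes") for d in data]
        g = assoc.group_correlation_test(recs, flags, bonferroni_m=16)
        out["traits"][trait] = {
            "selective_vs_zero": summarize(g["selective_vs_zero"]),
            "significant_after_bonferroni": g["selective_vs_zero_significant"]}

    lum = assoc.luminance_control([d for d in data if d.label != "none"], sess_of)
    for scope, res in lum.items():
        out["luminance"][scope] = summarize(res["group_test"])

    (ROOT / "results" / "06_associations.json").write_text(
        json.dumps(out, indent=2, default=float))
    print(json.dumps(out, indent=2, default=float))


if __name__ == "__main__":
    sys.exit(main())
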