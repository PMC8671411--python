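"""End-to-end orchestration over a synthetic cohort.

``run_all`` drives the full analysis sequence — simulate, validate, gaze
behavior, fixation/saccade selection, selectivity indices with permutation
nulls, cell-type metrics, population decoding, and saliency/luminance/trait
associations — and writes a machine-readable ``report.json`` plus a run
manifest with every seed needed to reproduce it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, metrics, selectivity
from .core import AnalysisConfig, validate_session
from .selectivity import NONE_CLASS
from .stats import chi2_2x2
from .synth import GeneratorConfig, generate_cohort

KNOWN_SECTIONS = {"generator", "analysis", "pipeline"}
PIPELINE_DEFAULTS = {"n_sessions": 12, "decode_runs": 10, "decode_folds": 8,
                     "decode_events_per_class": None, "seed": 0}


def load_config(config_path: str | Path) -> dict:
    cfg = json.loads(Path(config_path).read_text())
    unknown = set(cfg) - KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections {sorted(unknown)}")
    out = {"generator": GeneratorConfig(**cfg.get("generator", {})),
           "analysis": AnalysisConfig(**cfg.get("analysis", {})),
           "pipeline": {**PIPELINE_DEFAULTS, **cfg.get("pipeline", {})}}
    unknown = set(out["pipeline"]) - set(PIPELINE_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown pipeline keys {sorted(unknown)}")
    return out


def percent(k: int, n: int) -> str:
    return f"{100.0 * k / n:.2f}%" if n else "0.00%"


def _region_split(sessions, classes_by_session) -> dict:
    """Selective-unit counts split by amygdala vs pooled hippocampus."""
    from .core import pooled_region
    counts = {"amygdala": {"total": 0, "selective": 0, "eyes": 0},
              "hippocampus": {"total": 0, "selective": 0, "eyes": 0}}
    for s, classes in zip(sessions, classes_by_session):
        for u in s.units:
            reg = pooled_region(u.region)
            c = classes[u.unit_id]
            counts[reg]["total"] += 1
            if c.label != NONE_CLASS:
                counts[reg]["selective"] += 1
                if c.label == selectivity.EYES_PREFERRING:
                    counts[reg]["eyes"] += 1
    return counts


def run_all(config_path: str | Path, out_dir: str | Path) -> dict:
    t_begin = time.time()
    cfg = load_config(config_path)
    gen_cfg: GeneratorConfig = cfg["generator"]
    ana: AnalysisConfig = cfg["analysis"]
    pl = cfg["pipeline"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    report: dict = {}

    def mark(stage: str, t0: float) -> None:
        stages[stage] = round(time.time() - t0, 2)

    # -- simulate ------------------------------------------------------------
    t0 = time.time()
    cohort = generate_cohort(gen_cfg, pl["n_sessions"], seed=pl["seed"])
    sessions = [s for s, _ in cohort]
    truths = [t for _, t in cohort]
    mark("simulate", t0)

    # -- validate ------------------------------------------------------------
    t0 = time.time()
    reports = [validate_session(s, ana) for s in sessions]
    report["validation"] = {
        r.session_id: {"included": r.session_included,
                       "roi_fixation_counts": r.roi_fixation_counts,
                       "n_units_included": int(sum(r.unit_included.values()))}
        for r in reports}
    mark("validate", t0)

    # -- behavior ------------------------------------------------------------
    t0 = time.time()
    fix_shares = [behavior.fixation_shares(s) for s in sessions]
    first = behavior.first_fixation_shares(sessions)
    report["behavior"] = {
        "fixation_shares_mean": pd.DataFrame(
            [f.as_series() for f in fix_shares]).mean().to_dict(),
        "first_fixation_eyes_vs_mouth": first["eyes_vs_mouth"].to_dict()}
    mark("behavior", t0)

    # -- selection (fixation + saccade) --------------------------------------
    t0 = time.time()
    fix_classes = [selectivity.classify_units_fixation(s, ana) for s in sessions]
    sacc_classes = [selectivity.classify_units_saccade(s, ana) for s in sessions]
    all_fix = {u: c for m in fix_classes for u, c in m.items()}
    all_sacc = {u: c for m in sacc_classes for u, c in m.items()}
    n_total = len(all_fix)
    n_sel = sum(c.label != NONE_CLASS for c in all_fix.values())
    n_eyes = sum(c.label == selectivity.EYES_PREFERRING for c in all_fix.values())
    n_sacc_sel = sum(c.label != NONE_CLASS for c in all_sacc.values())
    region = _region_split(sessions, fix_classes)
    prevalence = {
        "fixation": {"selected": n_sel, "total": n_total,
                     "percent": percent(n_sel, n_total),
                     "binomial_p": selectivity.prevalence_test(n_sel, n_total, ana.alpha)},
        "saccade": {"selected": n_sacc_sel, "total": n_total,
                    "percent": percent(n_sacc_sel, n_total),
                    "binomial_p": selectivity.prevalence_test(n_sacc_sel, n_total, ana.alpha)},
        "eyes_preferring_share": percent(n_eyes, n_sel) if n_sel else None,
        "by_region": region}
    amy, hip = region["amygdala"], region["hippocampus"]
    if amy["total"] and hip["total"]:
        prevalence["amygdala_vs_hippocampus_chi2"] = chi2_2x2(
            amy["selective"], amy["total"] - amy["selective"],
            hip["selective"], hip["total"] - hip["selective"]).to_dict()
    overlap = selectivity.overlap_analysis(all_fix, all_sacc)
    prevalence["overlap"] = {k: (v.to_dict() if k == "test" else v)
                             for k, v in overlap.items()}
    report["prevalence"] = prevalence
    mark("select", t0)

    # -- FSI / permutation ---------------------------------------------------
    t0 = time.time()
    data_list = selectivity.cohort_event_data(sessions, fix_classes, ana)
    selective_data = [d for d in data_list if d.label != NONE_CLASS]
    fsi_summary = {}
    if len(selective_data) >= 2:
        records = selectivity.pooled_fsi(selective_data)
        cdf = selectivity.fsi_cdf_compare(records)
        perm = selectivity.permutation_mean_fsi(selective_data, ana, seed=pl["seed"])
        fsi_summary = {
            "eyes_vs_mouth_ks": cdf["test"].to_dict(),
            "permutation": {"observed_mean_fsi": perm["observed"],
                            "null_mean": float(np.mean(perm["null"])),
                            "p_value": perm["p_value"]}}
        try:
            fsi_summary["one_back_ks"] = selectivity.oneback_fsi(records)["test"].to_dict()
        except ValueError as exc:
            fsi_summary["one_back_ks"] = str(exc)
    report["fsi"] = fsi_summary
    mark("fsi", t0)

    # -- cell-type metrics ---------------------------------------------------
    t0 = time.time()
    metric_rows = {}
    for s in sessions:
        span = (float(s.trials["stim_onset"].iloc[0]),
                float(s.trials["stim_offset"].iloc[-1]))
        for u in s.units:
            metric_rows[u.unit_id] = metrics.unit_metrics(u, span)
    eyes_m = [metric_rows[u] for u, c in all_fix.items()
              if c.label == selectivity.EYES_PREFERRING]
    mouth_m = [metric_rows[u] for u, c in all_fix.items()
               if c.label == selectivity.MOUTH_PREFERRING]
    if len(eyes_m) >= 2 and len(mouth_m) >= 2:
        battery = metrics.compare_cell_types(eyes_m, mouth_m)
        report["cell_types"] = {k: (v.to_dict() if v is not None else None)
                                for k, v in battery.items()}
    mark("metrics", t0)

    # -- decoding ------------------------------------------------------------
    t0 = time.time()
    grid = decoding.make_bins()
    pseudo = decoding.build_pseudopopulation(
        sessions, grid, n_per_class=pl["decode_events_per_class"], seed=pl["seed"])
    curve = decoding.decode_sliding(pseudo, k_folds=pl["decode_folds"],
                                    n_runs=pl["decode_runs"], seed=pl["seed"])
    sig = decoding.decoding_significance(curve)
    table = decoding.curve_table(curve, sig)
    table.to_csv(out_dir / "decoding_curve.tsv", sep="\t", index=False)
    report["decoding"] = {"mean_accuracy": float(curve.mean.mean()),
                          "n_significant_bins": int(sig["fdr_mask"].sum()),
                          "n_bins": grid.n_bins,
                          "n_units": pseudo.n_units}
    mark("decode", t0)

    # -- associations --------------------------------------------------------
    t0 = time.time()
    from . import associations as assoc
    sessions_of = {}
    for s in sessions:
        for u in s.units:
            sessions_of[u.unit_id] = s
    sel_flag = {u: (c.label != NONE_CLASS) for u, c in all_fix.items()}
    sal_records = []
    for d in data_list:
        vals = assoc.saliency_values_for(d, sessions_of[d.unit_id])
        sal_records.append(assoc.fixation_value_correlation(
            d, vals, "saliency", "within_preferred"))
    sal_test = assoc.group_correlation_test(sal_records, sel_flag)
    report["associations"] = {"saliency_within_preferred": {
        k: (v.to_dict() if hasattr(v, "to_dict") else v)
        for k, v in sal_test.items()}}
    mark("associate", t0)

    report["headline"] = report_headline(report)
    manifest = {"config": {"generator": asdict(gen_cfg),
                           "analysis": asdict(ana), "pipeline": pl},
                "seed": pl["seed"],
                "stage_seconds": stages,
                "total_seconds": round(time.time() - t_begin, 2)}
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"report": report, "manifest": manifest}


def report_headline(report: dict) -> list[str]:
    """Compact text table of the headline counts and their tests."""
    prev = report.get("prevalence")
    if prev is None:
        raise ValueError("report lacks a prevalence section")
    lines = []
    f = prev["fixation"]
    lines.append(f"fixation-selective: {f['selected']}/{f['total']} "
                 f"({percent(f['selected'], f['total'])}), binomial "
                 f"p={f['binomial_p']:.3g}")
    s = prev["saccade"]
    lines.append(f"saccade-selective: {s['selected']}/{s['total']} "
                 f"({percent(s['selected'], s['total'])}), binomial "
                 f"p={s['binomial_p']:.3g}")
    if prev.get("eyes_preferring_share"):
        lines.append(f"eyes-preferring share of selective: "
                     f"{prev['eyes_preferring_share']}")
    if "amygdala_vs_hippocampus_chi2" in prev:
        chi = prev["amygdala_vs_hippocampus_chi2"]
        lines.append(f"amygdala vs hippocampus prevalence: chi2 "
                     f"p={chi['p_value']:.3g}")
    ov = prev.get("overlap")
    if ov:
        lines.append(f"fixation-selective among saccade-selective: "
                     f"{ov['n_both']}/{ov['n_saccade_selective']} vs "
                     f"{ov['n_fixation_selective']}/{ov['n_total']}, chi2 "
                     f"p={ov['test']['p_value']:.3g}")
    return lines
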