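"""Event-aligned selectivity analysis: unit classification, FSI/SSI,
permutation nulls, serial-order and one-back controls, PSTHs, ROC, and the
fixation/saccade selectivity overlap.

The analysis window for a fixation runs from 200 ms before fixation onset to
200 ms after fixation offset (mean length ~815 ms at the recorded fixation
durations); the saccade window is the fixed 400 ms around saccade onset. A
unit is *eyes-preferring* (resp. *mouth-preferring*) if its per-event window
rates differ between eyes and mouth events by a two-tailed two-sample t test
at ``alpha``, labeled by the sign of the mean difference.

The fixation-selectivity index (FSI) for event i of a unit is

    FSI_i = (FR_i - mean(FR_mouth)) / mean(FR_baseline) * 100%

multiplied by -1 when the *unit* is mouth-preferring (never as a function of
the event's ROI), so that selective units of both types average positive.
Its mean over mouth events is identically zero by construction. The
saccade-selectivity index (SSI) is the same construction on saccade windows
keyed by saccade target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnalysisConfig, Session, SpikeTrain, count_spikes
from .stats import (binom_upper_tail, chi2_2x2, ks_two_sample, spawn_rng,
                    t_two_sample)

EYES_PREFERRING = "eyes_preferring"
MOUTH_PREFERRING = "mouth_preferring"
NONE_CLASS = "none"


@dataclass
class UnitClass:
    """Per-unit eyes-vs-mouth classification."""

    unit_id: str
    label: str
    t_stat: float
    p_value: float
    n_eyes: int
    n_mouth: int


@dataclass
class UnitEventData:
    """One unit's per-event window rates, ready for index analyses.

    ``events`` carries the event rows (with ``roi`` holding the fixation ROI
    or the saccade target), aligned row-for-row with ``rates``. ``baseline``
    is the unit's mean pre-stimulus firing rate across trials.
    """

    unit_id: str
    events: pd.DataFrame
    rates: np.ndarray
    baseline: float
    label: str = NONE_CLASS

    def rates_for(self, roi: str) -> np.ndarray:
        return self.rates[(self.events["roi"] == roi).to_numpy()]


# ---------------------------------------------------------------------------
# windows and rates
# ---------------------------------------------------------------------------

def event_window(event, cfg: AnalysisConfig) -> tuple[float, float]:
    """Analysis window of a gaze event (half-open, seconds).

    Fixation: [onset - pre, offset + post); saccade: [onset - pre,
    onset + post) — the saccade window is anchored at saccade *onset* only.
    """
    if event["event_type"] == "fixation":
        return (float(event["t_start"]) - cfg.fixation_window_pre,
                float(event["t_end"]) + cfg.fixation_window_post)
    return (float(event["t_start"]) - cfg.saccade_window_pre,
            float(event["t_start"]) + cfg.saccade_window_post)


def _windows(events: pd.DataFrame, cfg: AnalysisConfig) -> np.ndarray:
    t0 = events["t_start"].to_numpy(dtype=float)
    t1 = events["t_end"].to_numpy(dtype=float)
    is_fix = (events["event_type"] == "fixation").to_numpy()
    lo = np.where(is_fix, t0 - cfg.fixation_window_pre, t0 - cfg.saccade_window_pre)
    hi = np.where(is_fix, t1 + cfg.fixation_window_post, t0 + cfg.saccade_window_post)
    return np.column_stack([lo, hi])


def event_window_rates(unit: SpikeTrain, events: pd.DataFrame,
                       cfg: AnalysisConfig) -> np.ndarray:
    """Mean firing rate (Hz) of ``unit`` in each event's analysis window."""
    win = _windows(events, cfg)
    counts = count_spikes(unit.spike_times, win)
    return counts / (win[:, 1] - win[:, 0])


def baseline_rate(unit: SpikeTrain, trials: pd.DataFrame,
                  cfg: AnalysisConfig) -> float:
    """Mean rate in the pre-stimulus baseline window, averaged across trials."""
    onsets = trials["stim_onset"].to_numpy(dtype=float)
    win = np.column_stack([onsets - cfg.baseline_window, onsets])
    counts = count_spikes(unit.spike_times, win)
    return float(np.mean(counts / cfg.baseline_window))


def unit_event_data(unit: SpikeTrain, session: Session, cfg: AnalysisConfig,
                    align: str = "fixation", label: str = NONE_CLASS) -> UnitEventData:
    """Assemble per-event rates for one unit.

    ``align="fixation"`` uses fixations keyed by their ROI;
    ``align="saccade"`` uses saccades keyed by their target ROI.
    """
    if align == "fixation":
        ev = session.fixations.copy()
    elif align == "saccade":
        ev = session.saccades.copy()
        ev["roi"] = ev["target_roi"]
    else:
        raise ValueError(f"unknown alignment {align!r}")
    ev = ev.merge(session.trials[["trial_id", "is_one_back"]], on="trial_id")
    rates = event_window_rates(unit, ev, cfg)
    return UnitEventData(unit_id=unit.unit_id, events=ev.reset_index(drop=True),
                         rates=rates, label=label,
                         baseline=baseline_rate(unit, session.trials, cfg))


# ---------------------------------------------------------------------------
# classification and prevalence
# ---------------------------------------------------------------------------

def classify_unit(data: UnitEventData, cfg: AnalysisConfig) -> UnitClass:
    eyes = data.rates_for("eyes")
    mouth = data.rates_for("mouth")
    if eyes.size < 2 or mouth.size < 2:
        return UnitClass(data.unit_id, NONE_CLASS, float("nan"), float("nan"),
                         eyes.size, mouth.size)
    res = t_two_sample(eyes, mouth, pooled=cfg.pooled_t)
    label = NONE_CLASS
    if res.p_value < cfg.alpha and res.statistic != 0.0:
        label = EYES_PREFERRING if eyes.mean() > mouth.mean() else MOUTH_PREFERRING
    return UnitClass(data.unit_id, label, res.statistic, res.p_value,
                     eyes.size, mouth.size)


def classify_units(session: Session, cfg: AnalysisConfig,
                   align: str = "fixation") -> dict[str, UnitClass]:
    """Eyes-vs-mouth classification of every unit in a session."""
    out = {}
    for unit in session.units:
        data = unit_event_data(unit, session, cfg, align=align)
        out[unit.unit_id] = classify_unit(data, cfg)
    return out


def classify_units_fixation(session: Session, cfg: AnalysisConfig) -> dict[str, UnitClass]:
    return classify_units(session, cfg, align="fixation")


def classify_units_saccade(session: Session, cfg: AnalysisConfig) -> dict[str, UnitClass]:
    return classify_units(session, cfg, align="saccade")


def prevalence_test(n_selected: int, n_total: int, alpha: float = 0.05) -> float:
    """Binomial upper-tail p for observing >= n_selected hits at rate alpha."""
    return binom_upper_tail(n_selected, n_total, alpha)


# ---------------------------------------------------------------------------
# FSI / SSI
# ---------------------------------------------------------------------------

def compute_fsi(data: UnitEventData) -> pd.DataFrame:
    """Per-event selectivity index for all events of a unit (all ROIs).

    Requires at least one mouth event and a positive baseline; the sign flip
    for mouth-preferring units depends only on the unit's label.
    """
    mouth = data.rates_for("mouth")
    if mouth.size < 1:
        raise ValueError(f"unit {data.unit_id} has no mouth events")
    if data.baseline <= 0:
        raise ValueError(f"unit {data.unit_id} has zero baseline rate; "
                         "excluded from index analyses")
    sign = -1.0 if data.label == MOUTH_PREFERRING else 1.0
    fsi = sign * (data.rates - mouth.mean()) / data.baseline * 100.0
    out = data.events[["event_id", "roi", "trial_id", "serial_order",
                       "is_one_back"]].copy()
    out.insert(0, "unit_id", data.unit_id)
    out["fsi_percent"] = fsi
    return out


def cohort_event_data(sessions, classes_by_session, cfg: AnalysisConfig,
                      align: str = "fixation") -> list[UnitEventData]:
    """Pool labeled per-unit event data across sessions."""
    pooled = []
    for session, classes in zip(sessions, classes_by_session):
        for unit in session.units:
            label = classes[unit.unit_id].label
            pooled.append(unit_event_data(unit, session, cfg, align=align,
                                          label=label))
    return pooled


def pooled_fsi(data_list: list[UnitEventData]) -> pd.DataFrame:
    """FSI records pooled across units, skipping zero-baseline units."""
    frames = []
    for d in data_list:
        if d.baseline <= 0 or d.rates_for("mouth").size < 1:
            continue
        frames.append(compute_fsi(d))
    if not frames:
        raise ValueError("no units eligible for FSI")
    return pd.concat(frames, ignore_index=True)


def fsi_cdf_compare(records: pd.DataFrame, roi_a: str = "eyes",
                    roi_b: str = "mouth") -> dict:
    """Two-sample KS comparison of pooled FSI distributions for two ROIs."""
    a = records.loc[records["roi"] == roi_a, "fsi_percent"].to_numpy()
    b = records.loc[records["roi"] == roi_b, "fsi_percent"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 FSI records per ROI ({roi_a}: {a.size}, "
                         f"{roi_b}: {b.size})")
    test = ks_two_sample(a, b)
    grid = np.sort(np.concatenate([a, b]))
    return {"test": test,
            "cdf_grid": grid,
            f"cdf_{roi_a}": np.searchsorted(np.sort(a), grid, side="right") / a.size,
            f"cdf_{roi_b}": np.searchsorted(np.sort(b), grid, side="right") / b.size}


def _mean_eye_fsi(rates: np.ndarray, is_eye: np.ndarray, sign: float,
                  baseline: float) -> float:
    # statistic for one unit under a given eye/mouth labeling
    mouth_mean = rates[~is_eye].mean()
    return float(sign * (rates[is_eye].mean() - mouth_mean) / baseline * 100.0)


def permutation_mean_fsi(data_list: list[UnitEventData],
                         cfg: AnalysisConfig, seed: int | None = None,
                         serial_orders: set[int] | None = None) -> dict:
    """Observed across-unit mean FSI over eye events vs a label-shuffled null.

    The statistic is the mean over units of each unit's mean FSI across its
    eye events. The null shuffles eye/mouth labels *within unit* (recomputing
    the mouth reference under the shuffle), ``cfg.n_permutations`` times;
    p = (1 + #{null >= observed}) / (1 + B). Restricting ``serial_orders``
    implements the fixation-serial-order control.
    """
    n_perm = cfg.n_permutations
    if n_perm < 100:
        import warnings
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    rng = spawn_rng(cfg.rng_seed if seed is None else seed, 7)

    per_unit = []
    for d in data_list:
        if d.baseline <= 0:
            continue
        ev = d.events
        keep = ev["roi"].isin(["eyes", "mouth"]).to_numpy()
        if serial_orders is not None:
            keep &= ev["serial_order"].isin(list(serial_orders)).to_numpy()
        rates = d.rates[keep]
        is_eye = (ev["roi"].to_numpy()[keep] == "eyes")
        if is_eye.sum() < 1 or (~is_eye).sum() < 1:
            continue
        sign = -1.0 if d.label == MOUTH_PREFERRING else 1.0
        per_unit.append((rates, is_eye, sign, d.baseline))
    if not per_unit:
        raise ValueError("no unit has both eye and mouth events in scope")

    observed = float(np.mean([_mean_eye_fsi(r, e, s, b) for r, e, s, b in per_unit]))
    null = np.empty(n_perm)
    for j in range(n_perm):
        vals = []
        for rates, is_eye, sign, base in per_unit:
            perm = rng.permutation(is_eye)
            vals.append(_mean_eye_fsi(rates, perm, sign, base))
        null[j] = np.mean(vals)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return {"observed": observed, "null": null, "p_value": float(p),
            "n_units": len(per_unit)}


def serial_order_fsi(data_list: list[UnitEventData], cfg: AnalysisConfig,
                     order_groups=((1,), (2,), (3, 4)),
                     seed: int | None = None) -> dict:
    """Permutation test restricted to fixations of given serial orders."""
    out = {}
    for group in order_groups:
        key = "+".join(map(str, group))
        try:
            out[key] = permutation_mean_fsi(data_list, cfg, seed=seed,
                                            serial_orders=set(group))
        except ValueError:
            out[key] = None  # not computable for this group
    return out


def oneback_fsi(records: pd.DataFrame) -> dict:
    """Eyes-vs-mouth FSI CDF comparison restricted to one-back repeat trials."""
    subset = records[records["is_one_back"].astype(bool)]
    if subset.empty:
        raise ValueError("no one-back repeat trials in the FSI records")
    return fsi_cdf_compare(subset)


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

@dataclass
class PsthResult:
    bin_centers: np.ndarray
    mean_rates: dict[str, np.ndarray]   # condition -> per-bin across-unit mean
    sem_rates: dict[str, np.ndarray]
    p_values: np.ndarray
    significant: np.ndarray             # Bonferroni mask over bins
    n_units: int


def psth(data_list: list[UnitEventData], cfg: AnalysisConfig,
         conditions: tuple[str, str] = ("eyes", "mouth"),
         span: tuple[float, float] = (-0.4, 0.8)) -> PsthResult:
    """Across-unit normalized PSTH with per-bin Bonferroni-corrected t tests.

    Spikes are counted in consecutive ``cfg.psth_bin`` bins aligned to event
    onset; each unit's binned rates are divided by its mean window rate over
    all analyzed events before averaging across units. Per-bin comparison is
    a two-tailed paired t test across units, Bonferroni-corrected over bins.
    """
    if len(data_list) < 2:
        raise ValueError("need >= 2 units for a group PSTH")
    width = cfg.psth_bin
    n_bins = int(round((span[1] - span[0]) / width))
    if n_bins < 1 or not np.isclose(span[0] + n_bins * width, span[1]):
        raise ValueError("bin grid does not tile the requested span")
    edges = span[0] + width * np.arange(n_bins + 1)
    centers = edges[:-1] + width / 2.0

    per_unit = {c: [] for c in conditions}
    for d in data_list:
        norm = d.rates.mean() if d.rates.size else 1.0
        if norm <= 0:
            norm = 1.0
        for cond in conditions:
            ev = d.events[d.events["roi"] == cond]
            onsets = ev["t_start"].to_numpy(dtype=float)
            if onsets.size == 0:
                per_unit[cond].append(np.full(n_bins, np.nan))
                continue
            lo = (onsets[:, None] + edges[None, :-1]).ravel()
            hi = (onsets[:, None] + edges[None, 1:]).ravel()
            # binned rates averaged over events, normalized per unit
            counts = count_spikes(_unit_spikes(d), np.column_stack([lo, hi]))
            rates = counts.reshape(onsets.size, n_bins).mean(axis=0) / width
            per_unit[cond].append(rates / norm)

    stacked = {c: np.vstack(per_unit[c]) for c in conditions}
    mean = {c: np.nanmean(stacked[c], axis=0) for c in conditions}
    sem = {c: np.nanstd(stacked[c], axis=0, ddof=1)
           / np.sqrt(np.sum(~np.isnan(stacked[c][:, 0]))) for c in conditions}

    a, b = conditions
    p = np.ones(n_bins)
    for k in range(n_bins):
        xa, xb = stacked[a][:, k], stacked[b][:, k]
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() >= 2:
            diff = xa[ok] - xb[ok]
            if np.var(diff) == 0.0:
                p[k] = 1.0 if diff.mean() == 0 else 0.0
            else:
                from .stats import t_paired
                p[k] = t_paired(xa[ok], xb[ok]).p_value
    sig = p < cfg.alpha / n_bins
    return PsthResult(bin_centers=centers, mean_rates=mean, sem_rates=sem,
                      p_values=p, significant=sig, n_units=len(data_list))


def _unit_spikes(data: UnitEventData) -> np.ndarray:
    if not hasattr(data, "_spike_cache"):
        raise AttributeError("UnitEventData lacks attached spikes; build via "
                             "unit_event_data_with_spikes")
    return data._spike_cache


def unit_event_data_with_spikes(unit: SpikeTrain, session: Session,
                                cfg: AnalysisConfig, align: str = "fixation",
                                label: str = NONE_CLASS) -> UnitEventData:
    """Like :func:`unit_event_data` but keeps the spike times for PSTHs."""
    d = unit_event_data(unit, session, cfg, align=align, label=label)
    d._spike_cache = unit.spike_times
    return d


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc_counts(counts_a: np.ndarray, counts_b: np.ndarray,
                   n_thresholds: int = 20) -> float:
    """AUC of the spike-count ROC with linearly spaced thresholds.

    Thresholds span [min, max] of the pooled counts inclusive; the class with
    the higher overall mean count is the positive class, so the area is at or
    above 0.5 by construction. Integration is by the trapezoid rule.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 events per class")
    pos, neg = (a, b) if a.mean() >= b.mean() else (b, a)
    lo, hi = min(pos.min(), neg.min()), max(pos.max(), neg.max())
    if lo == hi:
        return 0.5
    thresholds = np.linspace(lo, hi, n_thresholds)
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    # anchor the curve at (0,0) beyond the maximal count and sort by FPR
    fpr = np.concatenate([[0.0], fpr[::-1]])
    tpr = np.concatenate([[0.0], tpr[::-1]])
    auc = float(np.trapezoid(tpr, fpr))
    return max(auc, 1.0 - auc)


def roc_auc(unit: SpikeTrain, events_a: pd.DataFrame, events_b: pd.DataFrame,
            cfg: AnalysisConfig) -> float:
    """ROC AUC on spike counts in the analysis windows of two event sets."""
    wa, wb = _windows(events_a, cfg), _windows(events_b, cfg)
    return roc_auc_counts(count_spikes(unit.spike_times, wa),
                          count_spikes(unit.spike_times, wb))


# ---------------------------------------------------------------------------
# overlap of fixation and saccade selectivity
# ---------------------------------------------------------------------------

def overlap_analysis(fix_classes: dict[str, UnitClass],
                     sacc_classes: dict[str, UnitClass]) -> dict:
    """Is fixation selectivity over-represented among saccade-selective units?

    Builds the 2x2 table [fixation-selective, not | among saccade-selective
    units ; among the whole population] and applies the uncorrected
    chi-square.
    """
    if set(fix_classes) != set(sacc_classes):
        raise ValueError("classifications cover different unit sets")
    units = list(fix_classes)
    fix_sel = {u for u in units if fix_classes[u].label != NONE_CLASS}
    sacc_sel = {u for u in units if sacc_classes[u].label != NONE_CLASS}
    n_both = len(fix_sel & sacc_sel)
    n_sacc_only = len(sacc_sel - fix_sel)
    n_total = len(units)
    test = chi2_2x2(n_both, n_sacc_only, len(fix_sel), n_total - len(fix_sel))
    return {"n_both": n_both, "n_saccade_selective": len(sacc_sel),
            "n_fixation_selective": len(fix_sel), "n_total": n_total,
            "test": test}
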