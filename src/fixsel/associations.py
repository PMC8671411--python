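"""Per-fixation correlations of firing with external scalar maps.

Correlates each unit's per-fixation window firing rate with a scalar defined
per fixation — a saliency value under the fixated location, the viewed
face's ROI luminance, or the face's consensus social-trait rating — within a
declared ROI scope (fixations on the eyes, the mouth, inside or outside the
preferred eyes∪mouth region). Scoping matters: eyes and mouth differ
systematically in both luminance and neural response, so an unscoped
correlation would be confounded by the ROI contrast itself. Group-level
tests then compare the per-unit correlation coefficients against zero and
between feature-selective and non-selective units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Session
from .selectivity import UnitEventData
from .stats import bonferroni_threshold, t_one_sample, t_two_sample

MIN_FIXATIONS = 10  # below this a Pearson r is too unstable to report

PREFERRED_ROIS = ("eyes", "mouth")


@dataclass
class CorrelationRecord:
    unit_id: str
    variable: str
    roi_scope: str
    pearson_r: float | None
    p_value: float | None
    n_fixations: int
    flagged: bool = False


def _scope_mask(rois: np.ndarray, roi_scope: str) -> np.ndarray:
    if roi_scope == "within_preferred":
        return np.isin(rois, PREFERRED_ROIS)
    if roi_scope == "outside_preferred":
        return ~np.isin(rois, PREFERRED_ROIS)
    if roi_scope in ("eyes", "mouth", "nose", "other"):
        return rois == roi_scope
    raise ValueError(f"unknown roi_scope {roi_scope!r}")


def fixation_value_correlation(data: UnitEventData, values: np.ndarray,
                               variable: str, roi_scope: str,
                               min_fixations: int = MIN_FIXATIONS
                               ) -> CorrelationRecord:
    """Pearson r between per-fixation firing rate and a per-fixation scalar.

    ``values`` aligns row-for-row with ``data.events``. Records with fewer
    than ``min_fixations`` defined values in scope, or with constant rates or
    values, are flagged and carry no coefficient.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(data.events):
        raise ValueError("values must align with the unit's events")
    mask = _scope_mask(data.events["roi"].to_numpy(), roi_scope)
    mask &= ~np.isnan(values)
    x = data.rates[mask]
    v = values[mask]
    if x.size < min_fixations or np.std(x) == 0 or np.std(v) == 0:
        return CorrelationRecord(data.unit_id, variable, roi_scope, None, None,
                                 int(x.size), flagged=True)
    r, p = sps.pearsonr(x, v)
    return CorrelationRecord(data.unit_id, variable, roi_scope, float(r),
                             float(p), int(x.size))


def group_correlation_test(records: list[CorrelationRecord],
                           selective: dict[str, bool],
                           bonferroni_m: int = 1) -> dict:
    """Per-group one-sample t against 0 and the selective-vs-non contrast.

    Flagged records are excluded. ``bonferroni_m`` is the size of the test
    family (e.g. 8 traits x 2 scopes = 16); the returned significance flags
    use the adjusted threshold alpha/m at alpha = 0.05.
    """
    rs = {True: [], False: []}
    for rec in records:
        if rec.flagged or rec.pearson_r is None:
            continue
        rs[bool(selective[rec.unit_id])].append(rec.pearson_r)
    sel = np.array(rs[True])
    non = np.array(rs[False])
    thr = bonferroni_threshold(0.05, bonferroni_m)
    out: dict = {"bonferroni_threshold": thr}
    out["selective_vs_zero"] = t_one_sample(sel) if sel.size >= 2 else None
    out["nonselective_vs_zero"] = t_one_sample(non) if non.size >= 2 else None
    out["selective_vs_nonselective"] = (t_two_sample(sel, non)
                                        if sel.size >= 2 and non.size >= 2 else None)
    for key in ("selective_vs_zero", "nonselective_vs_zero",
                "selective_vs_nonselective"):
        res = out[key]
        out[f"{key}_significant"] = bool(res and res.p_value < thr)
    out["n_selective"], out["n_nonselective"] = sel.size, non.size
    return out


def saliency_values_for(data: UnitEventData, session: Session) -> np.ndarray:
    """Per-fixation saliency values aligned with a unit's event rows."""
    return session.saliency_for(data.events["event_id"])


def luminance_values_for(data: UnitEventData, session: Session) -> np.ndarray:
    """The viewed face's luminance of the fixated ROI, per fixation."""
    face_of_trial = session.trials.set_index("trial_id")["face_id"]
    faces = session.faces.set_index("face_id")
    face_ids = face_of_trial.loc[data.events["trial_id"]].to_numpy()
    rois = data.events["roi"].to_numpy()
    return np.array([faces.at[f, f"lum_{r}"] for f, r in zip(face_ids, rois)],
                    dtype=float)


def trait_values_for(data: UnitEventData, session: Session,
                     trait: str) -> np.ndarray:
    """The viewed face's consensus rating for one trait, per fixation."""
    face_of_trial = session.trials.set_index("trial_id")["face_id"]
    faces = session.faces.set_index("face_id")
    face_ids = face_of_trial.loc[data.events["trial_id"]].to_numpy()
    return faces.loc[face_ids, f"trait_{trait}"].to_numpy(dtype=float)


def luminance_control(data_list: list[UnitEventData],
                      sessions_of: dict[str, Session]) -> dict:
    """Per-unit luminance correlations within eyes, within mouth, outside both.

    A flat group-mean r near zero indicates the ROI selectivity is not a
    brightness response.
    """
    records = {"eyes": [], "mouth": [], "outside_preferred": []}
    for d in data_list:
        session = sessions_of[d.unit_id]
        lum = luminance_values_for(d, session)
        for scope in records:
            records[scope].append(
                fixation_value_correlation(d, lum, "luminance", scope))
    out = {}
    for scope, recs in records.items():
        rs = np.array([r.pearson_r for r in recs if not r.flagged])
        out[scope] = {"records": recs,
                      "group_test": t_one_sample(rs) if rs.size >= 2 else None}
    return out


def trait_rating_reduce(ratings: pd.DataFrame, mode: str = "consensus"
                        ) -> pd.Series:
    """Collapse per-rater ratings (columns: face_id, rater_id, rating) to a
    per-face value: the across-rater arithmetic mean (consensus)."""
    if mode not in ("consensus", "per_rater"):
        raise ValueError(f"unknown mode {mode!r}")
    if ratings.empty:
        raise ValueError("no ratings supplied")
    if mode == "per_rater":
        return ratings.set_index(["face_id", "rater_id"])["rating"]
    return ratings.groupby("face_id")["rating"].mean()
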