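"""Behavioral summaries of gaze: per-ROI shares and the first-fixation bias."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ROIS, Session
from .stats import t_paired


@dataclass
class RoiShares:
    """Per-ROI percentage of gaze events within one session."""

    shares: dict[str, float]
    n_events: int
    session_id: str
    normalization: str = "none"  # or "by_area"

    def as_series(self) -> pd.Series:
        return pd.Series({roi: self.shares[roi] for roi in ROIS})


def _shares_from_counts(counts: pd.Series, session: Session,
                        normalization: str) -> RoiShares:
    counts = counts.reindex(ROIS, fill_value=0).astype(float)
    n = int(counts.sum())
    if n == 0:
        raise ValueError(f"session {session.session_id} has no events to summarize")
    if normalization == "by_area":
        # weight counts by 1/mean ROI area before renormalizing to 100%
        areas = {roi: float(session.faces[f"area_{roi}"].mean()) for roi in ROIS}
        counts = counts / pd.Series(areas)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    pct = 100.0 * counts / counts.sum()
    return RoiShares(shares=pct.to_dict(), n_events=n,
                     session_id=session.session_id, normalization=normalization)


def fixation_shares(session: Session, normalization: str = "none") -> RoiShares:
    """Percentage of fixations landing on each ROI."""
    return _shares_from_counts(session.fixations["roi"].value_counts(),
                               session, normalization)


def saccade_shares(session: Session, normalization: str = "none") -> RoiShares:
    """Percentage of saccades directed at each ROI (by ``target_roi``)."""
    sac = session.saccades
    if sac.empty:
        raise ValueError(f"session {session.session_id} has no saccades")
    return _shares_from_counts(sac["target_roi"].value_counts(), session, normalization)


def first_fixation_shares(sessions: list[Session]) -> dict:
    """Per-session ROI shares of first fixations plus an eyes-vs-mouth paired t.

    The first fixation of a trial is the serial-order-1 fixation beginning
    after stimulus onset (the participant starts each trial on a central
    cross, so a carried-over fixation cannot be serial-order 1).
    """
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions for the paired comparison")
    rows = []
    for s in sessions:
        fix = s.fixations
        onsets = s.trials.set_index("trial_id")["stim_onset"]
        first = fix[(fix["serial_order"] == 1)
                    & (fix["t_start"].to_numpy()
                       > onsets.loc[fix["trial_id"]].to_numpy())]
        if first.empty:
            raise ValueError(f"session {s.session_id} has no first fixations")
        counts = first["roi"].value_counts().reindex(ROIS, fill_value=0)
        pct = 100.0 * counts / counts.sum()
        rows.append(pct.rename(s.session_id))
    table = pd.DataFrame(rows)
    test = t_paired(table["eyes"].to_numpy(), table["mouth"].to_numpy())
    return {"per_session": table, "eyes_vs_mouth": test}
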