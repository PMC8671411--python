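"""Domain types, session container, delimited-table I/O, and inclusion rules.

A *session* is one sitting of the face-viewing one-back task: a time-ordered
list of 1-s face presentations, the fixations and saccades the participant
made on each face (labeled by the facial region of interest they land on or
target), the spike trains of the simultaneously recorded units, and per-face
metadata (ROI luminance/area, social-trait ratings, per-fixation saliency
values).

Events and trials are held as pandas DataFrames with fixed column contracts;
spike trains are light dataclasses wrapping sorted numpy arrays. Everything
round-trips losslessly through a directory of TSV files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REGIONS = ("amygdala", "hippocampus_anterior", "hippocampus_posterior")
ROIS = ("eyes", "mouth", "nose", "other")
TRAITS = ("warm", "critical", "competent", "practical",
          "feminine", "strong", "youthful", "charismatic")

#: hippocampal subregions are pooled under this label for regional contrasts
HIPPOCAMPUS_POOLED = "hippocampus"

EVENT_COLUMNS = ["event_id", "event_type", "t_start", "t_end", "roi",
                 "trial_id", "serial_order", "target_roi"]
TRIAL_COLUMNS = ["trial_id", "face_id", "identity_id", "stim_onset",
                 "stim_offset", "is_one_back"]

_TIME_FMT = "%.6f"


def pooled_region(region: str) -> str:
    """Map a region label to the amygdala/hippocampus dichotomy."""
    if region == "amygdala":
        return "amygdala"
    if region in ("hippocampus_anterior", "hippocampus_posterior", HIPPOCAMPUS_POOLED):
        return HIPPOCAMPUS_POOLED
    raise ValueError(f"unknown region {region!r}")


@dataclass
class SpikeTrain:
    """One unit's sorted spike times plus its mean action-potential waveform."""

    unit_id: str
    session_id: str
    region: str
    spike_times: np.ndarray
    mean_waveform: np.ndarray
    sample_interval_ms: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r} for unit {self.unit_id}")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError(f"spike times of unit {self.unit_id} not strictly increasing")
        if self.sample_interval_ms <= 0:
            raise ValueError("waveform sample interval must be positive")
        if self.mean_waveform.size < 3:
            raise ValueError("waveform needs >= 3 samples")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    Windows are in seconds. The fixation window runs from ``fixation_window_pre``
    before fixation onset to ``fixation_window_post`` after fixation *offset*
    (so its length tracks the fixation duration); the saccade window is fixed
    around saccade *onset*. ``baseline_window`` is the pre-stimulus interval
    used to normalize selectivity indices. ``min_rate_hz`` and
    ``min_fix_per_roi`` are the unit/session inclusion thresholds (both
    inclusive bounds).
    """

    alpha: float = 0.05
    fixation_window_pre: float = 0.2
    fixation_window_post: float = 0.2
    saccade_window_pre: float = 0.2
    saccade_window_post: float = 0.2
    baseline_window: float = 0.5
    min_rate_hz: float = 0.15
    min_fix_per_roi: int = 10
    psth_bin: float = 0.05
    n_permutations: int = 1000
    pooled_t: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_window", "psth_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fixation_window_pre", "fixation_window_post",
                     "saccade_window_pre", "saccade_window_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class Session:
    """Trials + gaze events + spike trains + face metadata, validated jointly."""

    session_id: str
    patient_id: str
    trials: pd.DataFrame
    events: pd.DataFrame
    units: list[SpikeTrain]
    faces: pd.DataFrame
    saliency: pd.DataFrame  # columns: fixation_id (-> event_id), saliency_value

    def __post_init__(self) -> None:
        self.validate_structure()

    # -- structural integrity ------------------------------------------------
    def validate_structure(self) -> None:
        tr, ev = self.trials, self.events
        missing = set(TRIAL_COLUMNS) - set(tr.columns)
        if missing:
            raise ValueError(f"trials table missing columns {sorted(missing)}")
        missing = set(EVENT_COLUMNS) - set(ev.columns)
        if missing:
            raise ValueError(f"events table missing columns {sorted(missing)}")
        bad_roi = ~ev["roi"].isin(ROIS)
        if bad_roi.any():
            row = int(np.nonzero(bad_roi.to_numpy())[0][0])
            raise ValueError(f"unknown ROI label {ev['roi'].iloc[row]!r} in events row {row}")
        if (ev["t_start"] >= ev["t_end"]).any():
            raise ValueError("gaze events must have t_start < t_end")
        known = set(tr["trial_id"])
        orphan = ~ev["trial_id"].isin(known)
        if orphan.any():
            row = int(np.nonzero(orphan.to_numpy())[0][0])
            raise ValueError(f"events row {row} references unknown trial_id "
                             f"{ev['trial_id'].iloc[row]!r}")
        onsets = tr["stim_onset"].to_numpy()
        offsets = tr["stim_offset"].to_numpy()
        if np.any(offsets <= onsets) or np.any(np.diff(onsets) <= 0):
            raise ValueError("trials must be time-ordered and non-overlapping")
        # fixations must fall in the viewing span of their trial
        fix = ev[ev["event_type"] == "fixation"]
        span = tr.set_index("trial_id")
        lo = span.loc[fix["trial_id"], "stim_onset"].to_numpy() - 0.6
        hi = span.loc[fix["trial_id"], "stim_offset"].to_numpy() + 1.2
        if np.any(fix["t_start"].to_numpy() < lo) or np.any(fix["t_end"].to_numpy() > hi):
            raise ValueError("fixation outside the [onset-0.6, offset+1.2] viewing span")
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("unit ids must be unique within a session")

    # -- convenience views ---------------------------------------------------
    @property
    def fixations(self) -> pd.DataFrame:
        return self.events[self.events["event_type"] == "fixation"]

    @property
    def saccades(self) -> pd.DataFrame:
        return self.events[self.events["event_type"] == "saccade"]

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    @property
    def task_span(self) -> tuple[float, float]:
        """Start of the first trial's baseline to the last stimulus offset."""
        return (float(self.trials["stim_onset"].iloc[0]) - 0.5,
                float(self.trials["stim_offset"].iloc[-1]))

    def saliency_for(self, event_ids) -> np.ndarray:
        lut = self.saliency.set_index("fixation_id")["saliency_value"]
        return lut.reindex(event_ids).to_numpy(dtype=float)


@dataclass
class ValidationReport:
    """Inclusion decision for a session and each of its units."""

    session_id: str
    session_included: bool
    unit_included: dict[str, bool]
    roi_fixation_counts: dict[str, int]
    unit_rates_hz: dict[str, float]
    reasons: list[str] = field(default_factory=list)


def firing_rate_in_window(train: SpikeTrain, interval: tuple[float, float]) -> float:
    """Mean firing rate (Hz) over the half-open window [t0, t1).

    A spike exactly at t1 belongs to the *next* window, which makes counts
    additive over abutting windows.
    """
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError(f"degenerate interval [{t0}, {t1})")
    n = count_spikes(train.spike_times, np.array([[t0, t1]]))[0]
    return float(n) / (t1 - t0)


def count_spikes(spike_times: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Spike counts over an (n, 2) array of half-open [t0, t1) intervals."""
    intervals = np.asarray(intervals, dtype=float)
    lo = np.searchsorted(spike_times, intervals[:, 0], side="left")
    hi = np.searchsorted(spike_times, intervals[:, 1], side="left")
    return hi - lo


def validate_session(session: Session, cfg: AnalysisConfig | None = None) -> ValidationReport:
    """Apply the inclusion rules.

    The session is excluded if any ROI received fewer than ``min_fix_per_roi``
    fixations; a unit is excluded if its mean firing rate over the entire task
    is below ``min_rate_hz`` (inclusive threshold: a unit at exactly the
    threshold is kept). Report-only — nothing is mutated.
    """
    cfg = cfg or AnalysisConfig()
    fix = session.fixations
    counts = {roi: int((fix["roi"] == roi).sum()) for roi in ROIS}
    reasons = []
    session_ok = True
    for roi, n in counts.items():
        if n < cfg.min_fix_per_roi:
            session_ok = False
            reasons.append(f"only {n} fixations on {roi} "
                           f"(< {cfg.min_fix_per_roi})")
    t0, t1 = session.task_span
    rates, included = {}, {}
    for u in session.units:
        rate = firing_rate_in_window(u, (t0, t1))
        rates[u.unit_id] = rate
        ok = rate >= cfg.min_rate_hz
        included[u.unit_id] = ok
        if not ok:
            reasons.append(f"unit {u.unit_id} mean rate {rate:.3f} Hz "
                           f"< {cfg.min_rate_hz} Hz")
    return ValidationReport(session_id=session.session_id,
                            session_included=session_ok,
                            unit_included=included,
                            roi_fixation_counts=counts,
                            unit_rates_hz=rates,
                            reasons=reasons)


# ---------------------------------------------------------------------------
# delimited-table I/O
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, float_cols: tuple[str, ...] = (),
               fmt: str = _TIME_FMT) -> None:
    out = df.copy()
    for c in float_cols:
        if c in out.columns:
            out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else fmt % v)
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, na_rep="NA", lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to a directory of TSV tables (deterministic bytes)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    spikes = pd.DataFrame({
        "unit_id": np.concatenate([[u.unit_id] * u.n_spikes for u in session.units])
        if session.units else np.array([], dtype=object),
        "session_id": session.session_id,
        "region": np.concatenate([[u.region] * u.n_spikes for u in session.units])
        if session.units else np.array([], dtype=object),
        "spike_time_s": np.concatenate([u.spike_times for u in session.units])
        if session.units else np.array([], dtype=float),
    })
    if not session.units:
        spikes = pd.DataFrame(columns=["unit_id", "session_id", "region", "spike_time_s"])
    # 9 decimals so spikes separated by nanoseconds stay distinct on disk
    _write_tsv(spikes, path / "spikes.tsv", float_cols=("spike_time_s",),
               fmt="%.9f")

    wf_rows = []
    for u in session.units:
        for i, v in enumerate(u.mean_waveform):
            wf_rows.append((u.unit_id, i, v, u.sample_interval_ms))
    wf = pd.DataFrame(wf_rows, columns=["unit_id", "sample_index", "voltage",
                                        "sample_interval_ms"])
    _write_tsv(wf, path / "waveforms.tsv", float_cols=("voltage", "sample_interval_ms"))

    ev = session.events[EVENT_COLUMNS].copy()
    _write_tsv(ev, path / "events.tsv", float_cols=("t_start", "t_end"))

    tr = session.trials[TRIAL_COLUMNS].copy()
    tr["is_one_back"] = tr["is_one_back"].astype(int)
    _write_tsv(tr, path / "trials.tsv", float_cols=("stim_onset", "stim_offset"))

    float_face_cols = tuple(c for c in session.faces.columns
                            if c.startswith(("lum_", "area_", "trait_")))
    _write_tsv(session.faces, path / "faces.tsv", float_cols=float_face_cols)
    _write_tsv(session.saliency, path / "saliency.tsv", float_cols=("saliency_value",))

    meta = pd.DataFrame({"session_id": [session.session_id],
                         "patient_id": [session.patient_id]})
    _write_tsv(meta, path / "session.tsv")


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Enforces referential integrity and sorted spike times; a missing table or
    an unknown ROI label is fatal.
    """
    path = Path(path)
    tables = {}
    for name in ("spikes", "waveforms", "events", "trials", "faces",
                 "saliency", "session"):
        f = path / f"{name}.tsv"
        if not f.exists():
            raise FileNotFoundError(f"missing table {f}")
        tables[name] = pd.read_csv(f, sep="\t", na_values=["NA"], keep_default_na=False)

    meta = tables["session"]
    trials = tables["trials"].copy()
    trials["is_one_back"] = trials["is_one_back"].astype(bool)
    events = tables["events"].copy()
    events["target_roi"] = events["target_roi"].where(pd.notna(events["target_roi"]), None)

    units = []
    spikes, wf = tables["spikes"], tables["waveforms"]
    for unit_id, grp in wf.groupby("unit_id", sort=True):
        grp = grp.sort_values("sample_index")
        st = spikes[spikes["unit_id"] == unit_id]
        region = st["region"].iloc[0] if len(st) else "amygdala"
        times = np.sort(st["spike_time_s"].to_numpy(dtype=float))
        raw = spikes[spikes["unit_id"] == unit_id]["spike_time_s"].to_numpy(dtype=float)
        if raw.size and np.any(np.diff(raw) < 0):
            # tolerate file ordering but require strictly increasing after sort
            pass
        units.append(SpikeTrain(
            unit_id=str(unit_id),
            session_id=str(meta["session_id"].iloc[0]),
            region=str(region),
            spike_times=times,
            mean_waveform=grp["voltage"].to_numpy(dtype=float),
            sample_interval_ms=float(grp["sample_interval_ms"].iloc[0]),
        ))

    return Session(
        session_id=str(meta["session_id"].iloc[0]),
        patient_id=str(meta["patient_id"].iloc[0]),
        trials=trials,
        events=events,
        units=units,
        faces=tables["faces"],
        saliency=tables["saliency"],
    )
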