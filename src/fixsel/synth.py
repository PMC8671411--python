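"""Synthetic face-viewing sessions with planted ground truth.

Emulates the statistical structure the analyses assume: 500 one-second face
presentations with a 0.5–0.75 s jittered inter-stimulus interval and ~9%
one-back repeats; alternating saccade/fixation chains whose fixation ROI
sequence has a configurable stationary distribution (defaults: 22% eyes, 14%
mouth) with a first-fixation bias toward the eyes; and units firing as
piecewise-constant-rate Poisson processes, a configurable fraction of which
carry a multiplicative rate gain during fixations on their preferred ROI
(eyes or mouth), switched on — by default — already at the preceding
saccade's onset so that selectivity precedes fixation onset.

External scalar maps are planted through a latent per-fixation "drive":
selective units' rates during eyes/mouth fixations are modulated by the
drive, and saliency values / social-trait ratings are generated correlated
with it, which yields recoverable firing–saliency and firing–trait
correlations of tunable magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (ROIS, REGIONS, TRAITS, Session, SpikeTrain,
                   EVENT_COLUMNS, TRIAL_COLUMNS)
from .stats import spawn_rng

EYES_PREFERRING = "eyes_preferring"
MOUTH_PREFERRING = "mouth_preferring"
NONE_CLASS = "none"


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session.

    Defaults reproduce the recorded-task structure: trial count, ISI jitter,
    one-back fraction, ROI fixation proportions, mean fixation duration
    (0.415 s, so that the padded 200+duration+200 ms analysis window averages
    ~0.815 s), the prevalence of eyes-/mouth-preferring units (55/365 and
    19/365 of the population) and their rate gain during preferred-ROI
    fixations.
    """

    n_trials: int = 500
    n_units_per_region: dict = field(default_factory=lambda: {
        "amygdala": 15, "hippocampus_anterior": 12, "hippocampus_posterior": 4})
    frac_eyes_preferring: float = 55 / 365
    frac_mouth_preferring: float = 19 / 365
    gain_eyes: float = 2.0
    gain_mouth: float = 2.0
    nonselective_gain: float = 1.0
    gain_onset: str = "at_preceding_saccade_onset"  # or "at_fixation_onset"
    roi_stationary_probs: dict = field(default_factory=lambda: {
        "eyes": 0.22, "mouth": 0.14, "nose": 0.25, "other": 0.39})
    first_fixation_eye_bias: float = 0.10
    mean_fixation_duration_s: float = 0.415
    fixation_duration_cv: float = 0.4
    min_fixation_duration_s: float = 0.05
    saccade_duration_range: tuple = (0.02, 0.08)
    first_fixation_latency_range: tuple = (0.03, 0.12)
    baseline_rate_mean_hz: float = 3.0
    baseline_rate_log_sd: float = 0.6
    one_back_fraction: float = 0.09
    isi_jitter: tuple = (0.5, 0.75)
    fixation_drive_sd: float = 0.3
    saliency_effect_r: float = 0.3
    trait_effect_r: float = 0.3
    planted_traits: tuple = ("warm", "practical")
    n_identities: int = 50
    photos_per_identity: int = 10
    trough_to_peak_ms_range: tuple = (0.4, 1.1)
    waveform_sample_interval_ms: float = 1.0 / 32.0  # 32 kHz acquisition
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array([self.roi_stationary_probs[r] for r in ROIS])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("ROI stationary probabilities must sum to 1")
        if np.any(probs < 0):
            raise ValueError("ROI probabilities must be non-negative")
        for f in (self.frac_eyes_preferring, self.frac_mouth_preferring):
            if not (0.0 <= f <= 1.0):
                raise ValueError("selective fractions must lie in [0, 1]")
        if self.frac_eyes_preferring + self.frac_mouth_preferring > 1.0:
            raise ValueError("selective fractions sum above 1")
        if self.mean_fixation_duration_s <= 0 or self.min_fixation_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.gain_onset not in ("at_preceding_saccade_onset", "at_fixation_onset"):
            raise ValueError(f"unknown gain_onset {self.gain_onset!r}")

    @property
    def n_units(self) -> int:
        return int(sum(self.n_units_per_region.values()))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    unit_class: dict[str, str]
    unit_gain: dict[str, float]
    unit_baseline_hz: dict[str, float]
    event_drive: pd.DataFrame  # event_id, drive (latent modulation regressor)
    saliency_effect_r: float
    trait_effect_r: float
    planted_traits: tuple


# ---------------------------------------------------------------------------
# gaze chains
# ---------------------------------------------------------------------------

def _first_fix_probs(cfg: GeneratorConfig) -> np.ndarray:
    p = np.array([cfg.roi_stationary_probs[r] for r in ROIS], dtype=float)
    bias = cfg.first_fixation_eye_bias
    out = p.copy()
    out[0] = min(p[0] + bias, 1.0)
    rest = 1.0 - out[0]
    if p[0] < 1.0:
        out[1:] = p[1:] * rest / (1.0 - p[0])
    else:
        out[1:] = 0.0
    return out


def _lognormal_duration(cfg: GeneratorConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    cv = cfg.fixation_duration_cv
    sigma2 = np.log(1.0 + cv ** 2)
    mu = np.log(cfg.mean_fixation_duration_s) - sigma2 / 2.0
    d = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    return np.maximum(d, cfg.min_fixation_duration_s)


def simulate_gaze(cfg: GeneratorConfig, trial: pd.Series,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Alternating saccade/fixation chain for one trial.

    The fixation ROI sequence is drawn from a first-order chain whose
    stationary distribution equals ``roi_stationary_probs`` (independent
    draws — the simplest such chain); the first fixation gets an extra eye
    bias. Each saccade's ``target_roi`` is the next fixation's ROI; the chain
    starts with the saccade that leaves the central fixation cross.
    """
    onset = float(trial["stim_onset"])
    offset = float(trial["stim_offset"])
    p_first = _first_fix_probs(cfg)
    p_stat = np.array([cfg.roi_stationary_probs[r] for r in ROIS])
    # the second fixation compensates the first-fixation eye bias so the
    # overall ROI distribution stays at the configured stationary values
    p_second = np.clip(2.0 * p_stat - p_first, 0.0, None)
    p_second = p_second / p_second.sum()

    rows = []
    n_fix = 0
    t = onset + rng.uniform(*cfg.first_fixation_latency_range)
    while t < offset:
        p = p_first if n_fix == 0 else (p_second if n_fix == 1 else p_stat)
        roi = ROIS[rng.choice(len(ROIS), p=p)]
        sacc_dur = rng.uniform(*cfg.saccade_duration_range)
        fix_dur = float(_lognormal_duration(cfg, rng, 1)[0])
        fix_start = t + sacc_dur
        fix_end = min(fix_start + fix_dur, offset + 1.2)
        if fix_end <= fix_start or fix_start >= offset + 0.5:
            break
        n_fix += 1
        rows.append(("saccade", t, fix_start, roi, trial["trial_id"], n_fix, roi))
        rows.append(("fixation", fix_start, fix_end, roi, trial["trial_id"], n_fix, None))
        t = fix_end
    df = pd.DataFrame(rows, columns=["event_type", "t_start", "t_end", "roi",
                                     "trial_id", "serial_order", "target_roi"])
    return df


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _modulated_intervals(unit_class: str, events: pd.DataFrame,
                         cfg: GeneratorConfig, gain: float = 1.0) -> pd.DataFrame:
    """Fixation epochs during which a unit's rate is modulated.

    Selective units are modulated during *all* eyes and mouth fixations (the
    latent drive models shared feature salience); the preferred-ROI epochs
    additionally carry the class gain (``gained`` column) and are extended
    back to the preceding saccade's onset when configured. Units of class
    ``none`` with a non-unit gain model weak shared eye modulation
    (sub-threshold for single-unit selection but decodable at the population
    level); with gain 1.0 they are truly null.
    """
    pref = {"eyes_preferring": "eyes", "mouth_preferring": "mouth"}.get(unit_class)
    if pref is None and unit_class == NONE_CLASS and gain != 1.0:
        pref = "eyes"
    if pref is None:
        return pd.DataFrame(columns=["t0", "t1", "event_id", "gained"])
    rois = ("eyes", "mouth") if unit_class != NONE_CLASS else (pref,)
    fix = events[(events["event_type"] == "fixation") & events["roi"].isin(rois)]
    gained = (fix["roi"] == pref).to_numpy()
    if cfg.gain_onset == "at_preceding_saccade_onset":
        sac = events[events["event_type"] == "saccade"].set_index(
            ["trial_id", "serial_order"])
        t0 = []
        for g, (_, f) in zip(gained, fix.iterrows()):
            key = (f["trial_id"], f["serial_order"])
            t0.append(float(sac.loc[key, "t_start"]) if g and key in sac.index
                      else float(f["t_start"]))
    else:
        t0 = fix["t_start"].tolist()
    return pd.DataFrame({"t0": t0, "t1": fix["t_end"].to_numpy(),
                         "event_id": fix["event_id"].to_numpy(),
                         "gained": gained})


def simulate_spikes(unit_spec: dict, events: pd.DataFrame, trials: pd.DataFrame,
                    cfg: GeneratorConfig, rng: np.random.Generator,
                    event_drive: pd.Series | None = None) -> np.ndarray:
    """Piecewise-constant-rate Poisson spike train over the session span.

    ``unit_spec`` needs ``baseline_rate`` (Hz), ``class`` and ``gain``.
    The rate is ``baseline`` everywhere, multiplied by ``gain`` (and, when a
    drive series is given, by ``exp(sd*d - sd^2/2)``) inside the unit's
    modulated fixation epochs.
    """
    base = float(unit_spec["baseline_rate"])
    if base <= 0:
        raise ValueError("baseline rate must be positive")
    gain = float(unit_spec.get("gain", 1.0))
    span_start = float(trials["stim_onset"].iloc[0]) - 0.6
    span_end = float(trials["stim_offset"].iloc[-1]) + 1.5

    mod = _modulated_intervals(unit_spec["class"], events, cfg, gain=gain)
    # per-epoch multiplier: gain on preferred-ROI epochs, drive on all epochs
    mult = np.where(mod["gained"].to_numpy(dtype=bool), gain, 1.0) \
        if len(mod) else np.array([])
    if event_drive is not None and len(mod):
        sd = cfg.fixation_drive_sd
        d = event_drive.reindex(mod["event_id"]).to_numpy(dtype=float)
        mult = mult * np.exp(sd * d - sd ** 2 / 2.0)

    # breakpoints -> constant-rate segments
    edges = [span_start, span_end]
    edges.extend(mod["t0"].tolist())
    edges.extend(mod["t1"].tolist())
    edges = np.unique(np.clip(np.array(edges, dtype=float), span_start, span_end))
    seg_rate = np.full(edges.size - 1, base)
    mid = (edges[:-1] + edges[1:]) / 2.0
    for (t0, t1), m in zip(mod[["t0", "t1"]].to_numpy(), mult):
        inside = (mid >= t0) & (mid < t1)
        seg_rate[inside] = base * m

    spikes = []
    durs = np.diff(edges)
    counts = rng.poisson(seg_rate * durs)
    for (t0, dur), k in zip(zip(edges[:-1], durs), counts):
        if k:
            spikes.append(t0 + rng.uniform(0.0, dur, size=k))
    if not spikes:
        return np.array([], dtype=float)
    times = np.sort(np.concatenate(spikes))
    # enforce strict ordering with a 5 ns floor so 9-decimal text stays distinct
    dup = np.diff(times) < 5e-9
    while dup.any():
        times[1:][dup] += 5e-9
        times = np.sort(times)
        dup = np.diff(times) < 5e-9
    return times


def _biphasic_waveform(trough_to_peak_ms: float, sample_interval_ms: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Synthetic mean action potential: a trough followed by a slower peak."""
    n = 256
    t = np.arange(n) * sample_interval_ms
    t_trough = t[n // 4]
    t_peak = t_trough + trough_to_peak_ms
    wf = (-1.2 * np.exp(-((t - t_trough) ** 2) / (2 * 0.08 ** 2))
          + 0.6 * np.exp(-((t - t_peak) ** 2) / (2 * (0.35 * trough_to_peak_ms) ** 2)))
    wf += rng.normal(0.0, 0.01, size=n)
    return wf


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def _make_trials(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_trials
    face_pool = [f"face{(i // cfg.photos_per_identity):02d}_{i % cfg.photos_per_identity}"
                 for i in range(cfg.n_identities * cfg.photos_per_identity)]
    rng.shuffle(face_pool)
    is_rep = np.zeros(n, dtype=bool)
    n_rep = int(round(cfg.one_back_fraction * n))
    # place repeats so no two are adjacent (repeat chains have length 1)
    for pos in rng.permutation(np.arange(1, n)):
        if is_rep.sum() >= n_rep:
            break
        if not is_rep[pos - 1] and (pos + 1 >= n or not is_rep[pos + 1]):
            is_rep[pos] = True
    faces, fresh = [], iter(face_pool)
    for i in range(n):
        faces.append(faces[i - 1] if is_rep[i] and i > 0 else next(fresh))
    onset = 1.0
    rows = []
    for i in range(n):
        rows.append((f"t{i:04d}", faces[i], faces[i].split("_")[0], onset,
                     onset + 1.0, bool(is_rep[i])))
        onset += 1.0 + rng.uniform(*cfg.isi_jitter)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _make_faces(cfg: GeneratorConfig, trials: pd.DataFrame,
                face_drive: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    faces = sorted(trials["face_id"].unique())
    rows = []
    r = cfg.trait_effect_r
    for f in faces:
        row = {"face_id": f, "identity_id": f.split("_")[0]}
        # eyes darker than mouth by construction (shadows around the orbit)
        row["lum_eyes"] = float(np.clip(rng.normal(80, 10), 0, 255))
        row["lum_mouth"] = float(np.clip(rng.normal(120, 10), 0, 255))
        row["lum_nose"] = float(np.clip(rng.normal(110, 10), 0, 255))
        row["lum_other"] = float(np.clip(rng.normal(100, 10), 0, 255))
        row["area_eyes"] = float(rng.normal(4000, 300))
        row["area_mouth"] = float(rng.normal(3000, 250))
        row["area_nose"] = float(rng.normal(2500, 200))
        row["area_other"] = float(rng.normal(90000, 4000))
        d = float(face_drive.get(f, 0.0))
        for trait in TRAITS:
            base = rng.normal(4.0, 1.2)
            if trait in cfg.planted_traits:
                base = np.sqrt(1 - r ** 2) * (base - 4.0) + r * 1.2 * d + 4.0
            row[f"trait_{trait}"] = float(np.clip(base, 1.0, 7.0))
        rows.append(row)
    return pd.DataFrame(rows)


def generate_session(cfg: GeneratorConfig, session_id: str = "s00",
                     patient_id: str = "p00") -> tuple[Session, GroundTruth]:
    """One full synthetic session plus its planted ground truth."""
    rng = spawn_rng(cfg.seed, 0)
    trials = _make_trials(cfg, rng)

    chunks = []
    for _, trial in trials.iterrows():
        chunks.append(simulate_gaze(cfg, trial, rng))
    events = pd.concat(chunks, ignore_index=True)
    events.insert(0, "event_id", [f"e{i:05d}" for i in range(len(events))])
    events = events[EVENT_COLUMNS]

    fix_mask = events["event_type"] == "fixation"
    n_fix = int(fix_mask.sum())
    drive = pd.Series(rng.normal(0.0, 1.0, size=n_fix),
                      index=events.loc[fix_mask, "event_id"])

    # unit roster: classes assigned by configured prevalence
    n_units = cfg.n_units
    n_eyes = int(round(cfg.frac_eyes_preferring * n_units))
    n_mouth = int(round(cfg.frac_mouth_preferring * n_units))
    classes = ([EYES_PREFERRING] * n_eyes + [MOUTH_PREFERRING] * n_mouth
               + [NONE_CLASS] * (n_units - n_eyes - n_mouth))
    rng.shuffle(classes)
    regions = []
    for region in REGIONS:
        regions.extend([region] * cfg.n_units_per_region.get(region, 0))

    units, unit_class, unit_gain, unit_base = [], {}, {}, {}
    sigma = cfg.baseline_rate_log_sd
    mu = np.log(cfg.baseline_rate_mean_hz) - sigma ** 2 / 2.0
    for i, (klass, region) in enumerate(zip(classes, regions)):
        uid = f"{session_id}_u{i:03d}"
        base = float(rng.lognormal(mu, sigma))
        base = max(base, 0.3)  # keep units above the inclusion threshold
        gain = {EYES_PREFERRING: cfg.gain_eyes,
                MOUTH_PREFERRING: cfg.gain_mouth}.get(klass, cfg.nonselective_gain)
        spec = {"baseline_rate": base, "class": klass, "gain": gain}
        d = drive if klass != NONE_CLASS else None
        times = simulate_spikes(spec, events, trials, cfg, rng, event_drive=d)
        t2p = rng.uniform(*cfg.trough_to_peak_ms_range)
        wf = _biphasic_waveform(t2p, cfg.waveform_sample_interval_ms, rng)
        units.append(SpikeTrain(unit_id=uid, session_id=session_id, region=region,
                                spike_times=times, mean_waveform=wf,
                                sample_interval_ms=cfg.waveform_sample_interval_ms))
        unit_class[uid], unit_gain[uid], unit_base[uid] = klass, gain, base

    # saliency correlated with the drive; eyes/mouth offset higher
    rs = cfg.saliency_effect_r
    noise = rng.normal(0.0, 1.0, size=n_fix)
    s_latent = rs * drive.to_numpy() + np.sqrt(1.0 - rs ** 2) * noise
    roi_offset = events.loc[fix_mask, "roi"].map(
        {"eyes": 0.15, "mouth": 0.15, "nose": 0.0, "other": 0.0}).to_numpy()
    saliency_value = np.clip(0.4 + 0.12 * s_latent + roi_offset, 0.0, 1.0)
    saliency = pd.DataFrame({"fixation_id": events.loc[fix_mask, "event_id"].to_numpy(),
                             "saliency_value": saliency_value})

    fix_events = events[fix_mask]
    face_of_event = fix_events.merge(trials[["trial_id", "face_id"]], on="trial_id")
    face_drive = (pd.Series(drive.to_numpy(), index=face_of_event["face_id"].to_numpy())
                  .groupby(level=0).mean())
    sd = float(face_drive.std())
    if sd > 0:  # standardized so trait_effect_r is the face-level correlation
        face_drive = (face_drive - face_drive.mean()) / sd
    faces = _make_faces(cfg, trials, face_drive, rng)

    session = Session(session_id=session_id, patient_id=patient_id, trials=trials,
                      events=events, units=units, faces=faces, saliency=saliency)
    truth = GroundTruth(unit_class=unit_class, unit_gain=unit_gain,
                        unit_baseline_hz=unit_base,
                        event_drive=pd.DataFrame({"event_id": drive.index,
                                                  "drive": drive.to_numpy()}),
                        saliency_effect_r=rs, trait_effect_r=cfg.trait_effect_r,
                        planted_traits=cfg.planted_traits)
    from .core import validate_session
    report = validate_session(session)
    if not report.session_included:
        raise ValueError("generated session fails the fixation-count inclusion "
                         f"rule ({report.roi_fixation_counts}); raise n_trials or "
                         "the sparse ROI's stationary probability")
    return session, truth


def generate_cohort(cfg: GeneratorConfig, n_sessions: int,
                    seed: int | None = None) -> list[tuple[Session, GroundTruth]]:
    """Independent sessions with deterministic per-session sub-seeds."""
    if n_sessions < 1:
        raise ValueError("need at least one session")
    master = cfg.seed if seed is None else seed
    out = []
    for i in range(n_sessions):
        sub = int(spawn_rng(master, 100 + i).integers(0, 2 ** 31 - 1))
        scfg = GeneratorConfig(**{**cfg.__dict__, "seed": sub})
        out.append(generate_session(scfg, session_id=f"s{i:02d}",
                                    patient_id=f"p{i % 5:02d}"))
    return out
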