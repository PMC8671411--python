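"""Electrophysiological cell-type metrics and the group comparison battery.

Metrics are computed from all spikes fired over the experiment: the burst
index (fraction of inter-spike intervals strictly below 10 ms), the local
coefficient of variation CV2 = mean over adjacent ISI pairs of
2|ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i) (≈1 for Poisson firing, 0 for a
clock-regular train), and the trough-to-peak time of the mean waveform
(polarity-normalized so the trough precedes the peak), a standard proxy for
putative cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import SpikeTrain
from .stats import TestResult, chi2_2x2, ks_two_sample, t_two_sample

BURST_ISI_S = 0.010


@dataclass
class UnitMetrics:
    unit_id: str
    mean_rate_hz: float
    burst_index: float | None
    cv2: float | None
    trough_to_peak_ms: float | None
    waveform_inverted: bool


def burst_index(spike_times: np.ndarray) -> float:
    """Fraction of ISIs strictly shorter than 10 ms (boundary not counted)."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 2:
        raise ValueError("burst index needs >= 2 spikes")
    isis = np.diff(spike_times)
    return float(np.mean(isis < BURST_ISI_S))


def cv2(spike_times: np.ndarray) -> float:
    """Local coefficient of variation over adjacent ISI pairs.

    The sum runs over the |ISIs| - 1 adjacent pairs, each contributing
    2|ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 3:
        raise ValueError("CV2 needs >= 3 spikes (>= 2 ISIs)")
    isis = np.diff(spike_times)
    a, b = isis[:-1], isis[1:]
    return float(np.mean(2.0 * np.abs(b - a) / (b + a)))


def trough_to_peak(waveform: np.ndarray, sample_interval_ms: float
                   ) -> tuple[float, bool]:
    """Trough-to-peak time (ms) of a mean waveform, and whether polarity was
    inverted.

    The waveform polarity is flipped when the global maximum precedes the
    global minimum, so the trough always comes first; the peak is the global
    maximum among samples after the trough.
    """
    wf = np.asarray(waveform, dtype=float)
    if wf.size < 3:
        raise ValueError("waveform needs >= 3 samples")
    if np.ptp(wf) == 0:
        raise ValueError("flat waveform; trough-to-peak undefined")
    inverted = False
    if int(np.argmax(wf)) < int(np.argmin(wf)):
        wf = -wf
        inverted = True
    trough = int(np.argmin(wf))
    if trough >= wf.size - 1:
        raise ValueError("trough at the last sample; no subsequent peak")
    peak = trough + 1 + int(np.argmax(wf[trough + 1:]))
    return float((peak - trough) * sample_interval_ms), inverted


def unit_metrics(unit: SpikeTrain, trial_span: tuple[float, float]) -> UnitMetrics:
    """Full metric record for one unit.

    ``trial_span`` bounds the "entire duration of all valid trials" used for
    the mean rate; ISI metrics use every spike of the experiment.
    """
    t0, t1 = trial_span
    n_in = int(np.sum((unit.spike_times >= t0) & (unit.spike_times < t1)))
    rate = n_in / (t1 - t0)
    bi = burst_index(unit.spike_times) if unit.n_spikes >= 2 else None
    c = cv2(unit.spike_times) if unit.n_spikes >= 3 else None
    try:
        t2p, inv = trough_to_peak(unit.mean_waveform, unit.sample_interval_ms)
    except ValueError:
        t2p, inv = None, False
    return UnitMetrics(unit_id=unit.unit_id, mean_rate_hz=float(rate),
                       burst_index=bi, cv2=c, trough_to_peak_ms=t2p,
                       waveform_inverted=inv)


def compare_cell_types(group_a: list[UnitMetrics], group_b: list[UnitMetrics],
                       wide_threshold_ms: float = 0.5) -> dict:
    """Two-group comparison battery.

    t tests on mean rate, burst index, CV2 and trough-to-peak; a KS test on
    trough-to-peak; a chi-square on the proportion of units with
    trough-to-peak above ``wide_threshold_ms``; and the within-group Pearson
    correlation of mean rate with trough-to-peak.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 units per group")

    def col(group, attr):
        return np.array([getattr(m, attr) for m in group
                         if getattr(m, attr) is not None], dtype=float)

    report: dict = {}
    for attr in ("mean_rate_hz", "burst_index", "cv2", "trough_to_peak_ms"):
        xa, xb = col(group_a, attr), col(group_b, attr)
        report[f"t_{attr}"] = (t_two_sample(xa, xb)
                               if xa.size >= 2 and xb.size >= 2 else None)
    ta, tb = col(group_a, "trough_to_peak_ms"), col(group_b, "trough_to_peak_ms")
    report["ks_trough_to_peak"] = (ks_two_sample(ta, tb)
                                   if ta.size >= 2 and tb.size >= 2 else None)
    wa, wb = int((ta > wide_threshold_ms).sum()), int((tb > wide_threshold_ms).sum())
    try:
        report["chi2_wide_waveform"] = chi2_2x2(wa, ta.size - wa, wb, tb.size - wb)
    except ValueError:
        report["chi2_wide_waveform"] = None
    for name, group in (("a", group_a), ("b", group_b)):
        r_ = col(group, "mean_rate_hz")
        t_ = col(group, "trough_to_peak_ms")
        pairs = [(m.mean_rate_hz, m.trough_to_peak_ms) for m in group
                 if m.trough_to_peak_ms is not None]
        if len(pairs) >= 3 and np.std([p[0] for p in pairs]) > 0 \
                and np.std([p[1] for p in pairs]) > 0:
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            r, p = sps.pearsonr(x, y)
            report[f"rate_vs_t2p_{name}"] = TestResult(statistic=float(r),
                                                       p_value=float(p),
                                                       n=len(pairs))
        else:
            report[f"rate_vs_t2p_{name}"] = None
    return report
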