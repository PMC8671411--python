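"""Sliding-window pseudo-population decoding with the maximal-correlation-
coefficient (MCC) classifier.

Units recorded in different sessions are pooled into a pseudo-population:
for each unit, spike counts are taken in a grid of 500 ms bins stepped by
50 ms around event onset (27 bins from -600 ms, so the last bin is
[700, 1200) ms), and events of the two classes (eyes vs mouth) are matched
across units by label. Counts are z-scored per unit and bin using training-
fold statistics only, a mean template per class is estimated on the training
folds, and a held-out event is assigned to the class whose template has the
higher Pearson correlation with its population vector. Accuracy is averaged
over 8 stratified cross-validation folds and repeated over random splits;
per-bin significance against the 50% chance level counts the runs at or
below chance, with Benjamini–Hochberg correction across bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Session, count_spikes
from .stats import bh_fdr, spawn_rng


@dataclass(frozen=True)
class BinGrid:
    """Uniform sliding grid of half-open [t0, t1) bins relative to alignment."""

    start: float = -0.6
    width: float = 0.5
    step: float = 0.05
    n_bins: int = 27

    def __post_init__(self) -> None:
        if self.width <= 0 or self.step <= 0:
            raise ValueError("bin width and step must be positive")
        if self.n_bins < 1:
            raise ValueError("need at least one bin")

    @property
    def intervals(self) -> np.ndarray:
        t0 = self.start + self.step * np.arange(self.n_bins)
        return np.column_stack([t0, t0 + self.width])

    @property
    def centers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_bins) + self.width / 2.0


def make_bins(start: float = -0.6, width: float = 0.5, step: float = 0.05,
              n: int = 27) -> BinGrid:
    return BinGrid(start=start, width=width, step=step, n_bins=n)


@dataclass
class PseudoPopulation:
    """Count tensor (unit x event x bin) with balanced class labels."""

    counts: np.ndarray
    labels: np.ndarray          # per-event class label, shape (n_events,)
    unit_ids: list[str]
    grid: BinGrid
    unit_regions: list[str] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_events(self) -> int:
        return self.counts.shape[1]

    def subset_units(self, keep: np.ndarray) -> "PseudoPopulation":
        keep = np.asarray(keep)
        return PseudoPopulation(
            counts=self.counts[keep],
            labels=self.labels.copy(),
            unit_ids=[u for u, k in zip(self.unit_ids, keep) if k]
            if keep.dtype == bool else [self.unit_ids[i] for i in keep],
            grid=self.grid,
            unit_regions=[r for r, k in zip(self.unit_regions, keep) if k]
            if (self.unit_regions and keep.dtype == bool)
            else ([self.unit_regions[i] for i in keep] if self.unit_regions else []),
        )


def build_pseudopopulation(sessions: list[Session], grid: BinGrid,
                           align: str = "fixation",
                           classes: tuple[str, str] = ("eyes", "mouth"),
                           n_per_class: int | None = None,
                           seed: int = 0) -> PseudoPopulation:
    """Pool units across sessions into a balanced count tensor.

    Every unit contributes ``n_per_class`` events of each class (default: the
    largest count available to all units), subsampled deterministically from
    its own session's events.
    """
    rng = spawn_rng(seed, 11)
    per_session = []
    for s in sessions:
        if align == "fixation":
            ev = s.fixations
            key = ev["roi"]
            onsets = ev["t_start"].to_numpy(dtype=float)
        elif align == "saccade":
            ev = s.saccades
            key = ev["target_roi"]
            onsets = ev["t_start"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown alignment {align!r}")
        per_class_onsets = {c: onsets[(key == c).to_numpy()] for c in classes}
        per_session.append(per_class_onsets)

    avail = [min(len(p[c]) for c in classes) for p in per_session]
    cap = min(avail)
    if n_per_class is None:
        n_per_class = cap
    if cap < n_per_class or n_per_class < 1:
        short = classes[int(np.argmin([min(len(p[c]) for p in per_session)
                                       for c in classes]))]
        raise ValueError(f"insufficient events for class {short!r}: "
                         f"{cap} available, {n_per_class} requested")

    blocks, unit_ids, regions = [], [], []
    rel = grid.intervals
    for s, onset_map in zip(sessions, per_session):
        chosen = {c: np.sort(rng.choice(onset_map[c], size=n_per_class,
                                        replace=False)) for c in classes}
        onsets = np.concatenate([chosen[c] for c in classes])
        lo = (onsets[:, None] + rel[None, :, 0]).ravel()
        hi = (onsets[:, None] + rel[None, :, 1]).ravel()
        win = np.column_stack([lo, hi])
        for u in s.units:
            counts = count_spikes(u.spike_times, win)
            blocks.append(counts.reshape(onsets.size, grid.n_bins))
            unit_ids.append(u.unit_id)
            regions.append(u.region)
    labels = np.concatenate([[c] * n_per_class for c in classes])
    return PseudoPopulation(counts=np.stack(blocks), labels=labels,
                            unit_ids=unit_ids, grid=grid, unit_regions=regions)


# ---------------------------------------------------------------------------
# MCC classifier
# ---------------------------------------------------------------------------

def _row_corr(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with each row of t.

    Zero-variance rows (in either argument) get correlation 0 so that a
    silent population vector never dominates the argmax.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    tc = t - t.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    tn = np.linalg.norm(tc, axis=1)
    num = xc @ tc.T
    denom = np.outer(xn, tn)
    out = np.zeros_like(num)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def mcc_fit(train_vectors: np.ndarray, train_labels: np.ndarray) -> dict:
    """Per-class mean templates, keyed in sorted label order."""
    train_vectors = np.asarray(train_vectors, dtype=float)
    labels = np.asarray(train_labels)
    if train_vectors.shape[1] < 2:
        raise ValueError("feature vectors need length >= 2")
    classes = sorted(set(labels.tolist()))
    if any((labels == c).sum() < 1 for c in classes):
        raise ValueError("each class needs >= 1 training vector")
    return {c: train_vectors[labels == c].mean(axis=0) for c in classes}


def mcc_predict(templates: dict, x: np.ndarray):
    """Class whose template best correlates with ``x`` (ties: first in
    sorted label order)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    classes = sorted(templates)
    t = np.vstack([templates[c] for c in classes])
    corr = _row_corr(x, t)
    idx = np.argmax(corr, axis=1)  # argmax takes the first maximum on ties
    out = np.array([classes[i] for i in idx])
    return out if out.size > 1 else out[0]


# ---------------------------------------------------------------------------
# cross-validated sliding decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodingCurve:
    """Per-bin decoding accuracies across cross-validation runs."""

    accuracies: np.ndarray  # (n_runs, n_bins)
    grid: BinGrid
    chance: float = 0.5

    @property
    def mean(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        return self.accuracies.std(axis=0, ddof=1) / np.sqrt(self.accuracies.shape[0])


def decode_sliding(pseudo: PseudoPopulation, k_folds: int = 8,
                   n_runs: int = 50, seed: int = 0,
                   shuffle_labels: bool = False) -> DecodingCurve:
    """Stratified k-fold cross-validated MCC accuracy per bin, over runs.

    Each run draws a fresh stratified partition (classes subsampled to equal
    size first, making 50% the exact chance level), trains per bin on k-1
    folds — including the per-unit, per-bin z-scoring parameters — and tests
    on the held-out fold; a different classifier is trained for every bin.

    ``shuffle_labels=True`` permutes the class labels freshly on every run,
    the permutation-null construction whose run-averaged accuracy converges
    to the 50% chance level.
    """
    labels = pseudo.labels
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("decoding expects exactly two classes")
    idx_by_class = {c: np.nonzero(labels == c)[0] for c in classes}
    n_min = min(len(v) for v in idx_by_class.values())
    if n_min < k_folds:
        short = classes[int(np.argmin([len(idx_by_class[c]) for c in classes]))]
        raise ValueError(f"class {short!r} has {n_min} events; "
                         f"needs >= {k_folds} for {k_folds}-fold CV")
    counts = pseudo.counts.astype(float)
    n_bins = pseudo.grid.n_bins
    acc = np.zeros((n_runs, n_bins))
    rng = spawn_rng(seed, 13)

    base_labels = labels
    for run in range(n_runs):
        labels = rng.permutation(base_labels) if shuffle_labels else base_labels
        idx_by_class = {c: np.nonzero(labels == c)[0] for c in classes}
        fold_of = {}
        for c in classes:
            pick = rng.permutation(idx_by_class[c])[:n_min - (n_min % k_folds)]
            for f, chunk in enumerate(np.array_split(pick, k_folds)):
                for i in chunk:
                    fold_of[i] = f
        used = np.array(sorted(fold_of))
        folds = np.array([fold_of[i] for i in used])
        y = labels[used]
        x = counts[:, used, :]  # units x events x bins

        correct = np.zeros(n_bins)
        total = np.zeros(n_bins)
        for f in range(k_folds):
            test = folds == f
            xtr, xte = x[:, ~test, :], x[:, test, :]
            ytr, yte = y[~test], y[test]
            mu = xtr.mean(axis=1, keepdims=True)        # per unit per bin
            sd = xtr.std(axis=1, keepdims=True, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)              # zero-variance floor
            ztr = (xtr - mu) / sd
            zte = (xte - mu) / sd
            for b in range(n_bins):
                templates = {c: ztr[:, ytr == c, b].mean(axis=1) for c in classes}
                t = np.vstack([templates[c] for c in classes])
                corr = _row_corr(zte[:, :, b].T, t)
                pred = np.take(classes, np.argmax(corr, axis=1))
                correct[b] += np.sum(pred == yte)
                total[b] += yte.size
        acc[run] = correct / total
    return DecodingCurve(accuracies=acc, grid=pseudo.grid)


def decoding_significance(curve: DecodingCurve, chance: float = 0.5,
                          q: float = 0.05) -> dict:
    """Per-bin run-counting p against chance, with BH-FDR across bins.

    p(bin) = (1 + #{runs with accuracy <= chance}) / (1 + n_runs).
    """
    n_runs = curve.accuracies.shape[0]
    if n_runs < 2:
        raise ValueError("need >= 2 runs")
    below = (curve.accuracies <= chance).sum(axis=0)
    p = (1.0 + below) / (1.0 + n_runs)
    return {"p_values": p, "fdr_mask": bh_fdr(p, q), "chance": chance}


def compare_groups(curve_a: DecodingCurve, curve_b: DecodingCurve,
                   q: float = 0.05) -> dict:
    """Run-counting comparison of two decoding curves on the same grid."""
    if curve_a.accuracies.shape != curve_b.accuracies.shape:
        raise ValueError("curves have mismatched runs or grids")
    if not np.allclose(curve_a.grid.centers, curve_b.grid.centers):
        raise ValueError("curves use different bin grids")
    n_runs = curve_a.accuracies.shape[0]
    a_not_gt = (curve_a.accuracies <= curve_b.accuracies).sum(axis=0)
    p = (1.0 + a_not_gt) / (1.0 + n_runs)
    direction = np.where(curve_a.mean >= curve_b.mean, "a>b", "b>a")
    return {"p_values": p, "fdr_mask": bh_fdr(p, q), "direction": direction}


def curve_table(curve: DecodingCurve, sig: dict | None = None) -> pd.DataFrame:
    """Tidy per-bin summary (bin_center, mean_acc, sem, p, fdr_sig)."""
    df = pd.DataFrame({"bin_center": curve.grid.centers,
                       "mean_acc": curve.mean, "sem": curve.sem})
    if sig is not None:
        df["p"] = sig["p_values"]
        df["fdr_sig"] = sig["fdr_mask"]
    return df
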