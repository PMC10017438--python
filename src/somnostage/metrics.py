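"""Evaluation suite: confusion matrices, multiclass MCC (Gorodkin), F1,
accuracy, Cohen's kappa, stage proportions, transition rate, and the
light-sleep (N1+N2) merge.

All metrics operate per PSG; headline aggregation across PSGs is the
median (means are also reported, labelled as such).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_psg import Hypnogram, STAGES, UNKNOWN

logger = logging.getLogger(__name__)

LIGHT_STAGES = ("W", "LIGHT", "N3", "REM")
#: 5-class -> 4-class index map (N1 and N2 both -> LIGHT)
_LIGHT_MAP = np.array([0, 1, 1, 2, 3])


@dataclass
class ConfusionMatrix:
    """Integer count matrix, rows = true stage, columns = predicted stage."""

    counts: np.ndarray
    stage_order: tuple[str, ...] = STAGES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.stage_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / rows
        return np.where(rows > 0, out, 0.0)


def _paired_codes(true: Hypnogram, pred: Hypnogram) -> tuple[np.ndarray, np.ndarray]:
    if len(true) != len(pred):
        raise ValueError(f"hypnogram lengths differ: {len(true)} vs {len(pred)}")
    mask = (true.stages != UNKNOWN) & (pred.stages != UNKNOWN)
    return true.stages[mask], pred.stages[mask]


def confusion(true: Hypnogram, pred: Hypnogram) -> ConfusionMatrix:
    """5x5 counts with UNKNOWN epochs dropped pairwise."""
    t, p = _paired_codes(true, pred)
    k = len(STAGES)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (t.astype(int), p.astype(int)), 1)
    return ConfusionMatrix(counts)


def _check_nonempty(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("empty confusion matrix: no scored epochs")


def accuracy(cm: ConfusionMatrix) -> float:
    _check_nonempty(cm)
    return float(np.trace(cm.counts) / cm.total)


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin covariance form)."""
    _check_nonempty(cm)
    c = cm.counts.astype(np.float64)
    n = c.sum()
    trace = np.trace(c)
    t = c.sum(axis=1)  # true counts
    p = c.sum(axis=0)  # predicted counts
    cov_tp = trace * n - t @ p
    cov_tt = n * n - t @ t
    cov_pp = n * n - p @ p
    denom = np.sqrt(cov_tt * cov_pp)
    return float(cov_tp / denom) if denom > 0 else 0.0


def f1_per_stage(cm: ConfusionMatrix) -> np.ndarray:
    """F1 per stage; absent stages (no true and no predicted epochs) get 0."""
    _check_nonempty(cm)
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    out = np.zeros(len(cm.stage_order))
    present = denom > 0
    out[present] = 2 * tp[present] / denom[present]
    if (~present).any():
        absent = [cm.stage_order[i] for i in np.nonzero(~present)[0]]
        warnings.warn(f"stage(s) {absent} absent from both hypnograms; F1 set to 0",
                      stacklevel=2)
    return out


def f1_macro(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the per-stage F1 scores."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.mean(f1_per_stage(cm)))


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from the count matrix."""
    _check_nonempty(cm)
    c = cm.counts.astype(np.float64)
    n = c.sum()
    po = np.trace(c) / n
    pe = (c.sum(axis=1) @ c.sum(axis=0)) / (n * n)
    return float((po - pe) / (1.0 - pe)) if pe < 1.0 else 1.0


def stage_proportions(hyp: Hypnogram) -> np.ndarray:
    """Fraction of scored epochs per stage; sums to 1."""
    scored = hyp.stages[hyp.stages != UNKNOWN]
    if scored.size == 0:
        raise ValueError("all epochs are UNKNOWN")
    return np.bincount(scored, minlength=len(STAGES)) / scored.size


def transition_rate(hyp: Hypnogram, denominator: str = "n_minus_1") -> float:
    """Stage changes per epoch over UNKNOWN-free adjacent pairs.

    Default denominator is (length - 1); ``denominator='n'`` divides by
    the epoch count instead.
    """
    if len(hyp) < 2:
        raise ValueError("transition rate needs at least 2 epochs")
    a, b = hyp.stages[:-1], hyp.stages[1:]
    valid = (a != UNKNOWN) & (b != UNKNOWN)
    changes = int(((a != b) & valid).sum())
    if denominator == "n_minus_1":
        denom = int(valid.sum())
    elif denominator == "n":
        denom = len(hyp)
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if denom == 0:
        raise ValueError("no scorable adjacent epoch pairs")
    return changes / denom


def merge_light_sleep(obj: Hypnogram | ConfusionMatrix):
    """Merge N1 and N2 into LIGHT; 5-class input only."""
    if isinstance(obj, Hypnogram):
        merged = np.where(obj.stages == UNKNOWN, UNKNOWN,
                          _LIGHT_MAP[np.clip(obj.stages, 0, 4)]).astype(np.int8)
        return merged  # codes over LIGHT_STAGES order; UNKNOWN preserved
    if isinstance(obj, ConfusionMatrix):
        if obj.stage_order != STAGES:
            raise ValueError("confusion matrix is already merged")
        c = obj.counts
        out = np.zeros((4, 4), dtype=np.int64)
        for i in range(5):
            for j in range(5):
                out[_LIGHT_MAP[i], _LIGHT_MAP[j]] += c[i, j]
        return ConfusionMatrix(out, stage_order=LIGHT_STAGES)
    raise TypeError(f"cannot merge light sleep on {type(obj).__name__}")


def confusion_from_codes(t: np.ndarray, p: np.ndarray,
                         stage_order: tuple[str, ...]) -> ConfusionMatrix:
    k = len(stage_order)
    counts = np.zeros((k, k), dtype=np.int64)
    mask = (t != UNKNOWN) & (p != UNKNOWN)
    np.add.at(counts, (t[mask].astype(int), p[mask].astype(int)), 1)
    return ConfusionMatrix(counts, stage_order=stage_order)


def report(true: Hypnogram, pred: Hypnogram) -> dict:
    """Per-PSG metric bundle used by the CLI's eval command."""
    cm = confusion(true, pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_stage = f1_per_stage(cm)
    out = {
        "accuracy": accuracy(cm),
        "mcc": mcc(cm),
        "kappa": kappa(cm),
        "f1_macro": f1_macro(cm),
        "f1_per_stage": {s: float(v) for s, v in zip(STAGES, per_stage)},
        "confusion": cm.counts.tolist(),
        "stage_proportions_true": stage_proportions(true).tolist(),
        "stage_proportions_pred": stage_proportions(pred).tolist(),
    }
    if len(true) >= 2:
        out["transition_rate_true"] = transition_rate(true)
        out["transition_rate_pred"] = transition_rate(pred)
    return out


def aggregate(per_psg: list[dict]) -> dict:
    """Median (headline) and mean (labelled) across per-PSG reports."""
    keys = ("accuracy", "mcc", "kappa", "f1_macro")
    return {
        "median": {k: float(np.median([r[k] for r in per_psg])) for k in keys},
        "mean": {k: float(np.mean([r[k] for r in per_psg])) for k in keys},
        "n_psgs": len(per_psg),
    }
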