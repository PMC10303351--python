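"""Pixel-level artery/vein classification metrics.

Sensitivity (true-positive rate), precision (positive predictive value) and
their harmonic mean F1, reported per class and stage in percent:

    sensitivity = 100 * TP / (TP + FN)
    precision   = 100 * TP / (TP + FP)
    F1          = 2 * S * P / (S + P)

Counts are restricted to pixels that are vessels in the ground truth, so
the denominators are the true artery (vein) pixel populations; vessel
*detection* quality is reported separately as a Dice coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ARTERY, BACKGROUND, VEIN

CLASS_NAMES = {ARTERY: "artery", VEIN: "vein"}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def confusion_counts(pred: np.ndarray, truth: np.ndarray, cls: int) -> ConfusionCounts:
    """Per-class confusion counts over ground-truth vessel pixels only."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    domain = truth != BACKGROUND
    p = pred[domain] == cls
    t = truth[domain] == cls
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def sensitivity(c: ConfusionCounts) -> float:
    """Hit rate 100*TP/(TP+FN), percent."""
    if c.tp + c.fn == 0:
        raise ValueError("no ground-truth positives")
    return 100.0 * c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """Positive predictive value 100*TP/(TP+FP), percent."""
    if c.tp + c.fp == 0:
        raise ValueError("no predicted positives")
    return 100.0 * c.tp / (c.tp + c.fp)


def f1(sens: float, prec: float) -> float:
    """Harmonic mean of sensitivity and precision (same percent scale)."""
    if sens + prec == 0:
        raise ValueError("sensitivity and precision are both zero")
    return 2.0 * sens * prec / (sens + prec)


def metrics_table(results: dict[str, dict[int, ConfusionCounts]]) -> pd.DataFrame:
    """Tabulate per-stage, per-class metrics rounded to one decimal.

    ``results`` maps stage name -> {class -> aggregated ConfusionCounts}.
    """
    rows = []
    for stage_name, per_class in results.items():
        for cls, counts in per_class.items():
            s = sensitivity(counts)
            p = precision(counts)
            rows.append(
                {
                    "stage": stage_name,
                    "class": CLASS_NAMES.get(cls, str(cls)),
                    "sensitivity": round(s, 1),
                    "precision": round(p, 1),
                    "f1": round(f1(s, p), 1),
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                }
            )
    return pd.DataFrame(rows)


def stage_trend(table: pd.DataFrame) -> dict:
    """Check the severity trend: normal maximal and PDR minimal per series.

    For each class and indicator (sensitivity, precision, f1) across the
    four stages, reports whether the normal stage attains the strict
    maximum and PDR the strict minimum, plus an overall boolean.
    """
    required = {"normal", "BDR", "PPDR", "PDR"}
    present = set(table["stage"])
    if not required <= present:
        raise ValueError(f"missing stages: {sorted(required - present)}")
    report: dict = {"series": {}, "all_satisfied": True}
    for cls in sorted(table["class"].unique()):
        for indicator in ("sensitivity", "precision", "f1"):
            sub = table[table["class"] == cls].set_index("stage")[indicator]
            values = {st: float(sub[st]) for st in required}
            others_normal = [values[s] for s in required - {"normal"}]
            others_pdr = [values[s] for s in required - {"PDR"}]
            ok = values["normal"] > max(others_normal) and values["PDR"] < min(
                others_pdr
            )
            report["series"][f"{cls}_{indicator}"] = {
                "values": values,
                "normal_max_pdr_min": bool(ok),
            }
            report["all_satisfied"] = report["all_satisfied"] and ok
    return report
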