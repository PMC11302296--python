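"""Classification and segmentation quality metrics.

Everything derives from the 2×2 confusion matrix (rows = true class,
columns = predicted class) in the usual way: per-class precision, recall,
F1 and support; accuracy; macro (unweighted) and support-weighted
aggregates; the majority-class chance baseline; and per-class dice overlap
for the ternary segmentation masks, averaged over molecules at dataset
level. When both the predicted and true voxel sets of a class are empty,
that class's dice is defined as 1 so absent minority classes on small
grids do not spuriously zero the average.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .cube import TernaryMask

__all__ = [
    "EvaluationReport",
    "confusion_matrix",
    "classification_report",
    "chance_baseline",
    "dice_per_class",
    "average_dice",
]


@dataclass
class EvaluationReport:
    confusion: np.ndarray  # (2, 2) counts, rows true / cols predicted
    per_class: dict  # class -> dict(precision, recall, f1, support)
    accuracy: float
    macro: Tuple[float, float, float]  # precision, recall, f1
    weighted: Tuple[float, float, float]
    chance: float | None = None
    dice_per_class: Tuple[float, float, float] | None = None
    zero_division_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "macro": {"precision": self.macro[0], "recall": self.macro[1], "f1": self.macro[2]},
            "weighted": {"precision": self.weighted[0], "recall": self.weighted[1], "f1": self.weighted[2]},
            "chance": self.chance,
            "dice_per_class": list(self.dice_per_class) if self.dice_per_class is not None else None,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def text_table(self) -> str:
        """Aligned report mirroring the usual per-class metric table layout."""
        lines = [f"{'Class':<12}{'Precision':>10}{'Recall':>10}{'F1 score':>10}{'Support':>9}"]
        total = int(self.confusion.sum())
        for c in (0, 1):
            m = self.per_class[c]
            lines.append(
                f"{'Class ' + str(c):<12}{m['precision']:>10.2f}{m['recall']:>10.2f}"
                f"{m['f1']:>10.2f}{m['support']:>9d}"
            )
        lines.append(f"{'Accuracy':<12}{'':>10}{'':>10}{self.accuracy:>10.2f}{total:>9d}")
        lines.append(
            f"{'Macro':<12}{self.macro[0]:>10.2f}{self.macro[1]:>10.2f}"
            f"{self.macro[2]:>10.2f}{total:>9d}"
        )
        lines.append(
            f"{'Weighted':<12}{self.weighted[0]:>10.2f}{self.weighted[1]:>10.2f}"
            f"{self.weighted[2]:>10.2f}{total:>9d}"
        )
        if self.chance is not None:
            lines.append(f"Chance prediction: {self.chance:.1%}")
        if self.dice_per_class is not None:
            lines.append(
                "Dice per segmentation class: "
                + ", ".join(f"{d:.4f}" for d in self.dice_per_class)
            )
        return "\n".join(lines)


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int]) -> np.ndarray:
    """2×2 count matrix; entry (t, p) counts true-t samples predicted p."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise ValueError("empty label sequences")
    for name, arr in (("y_true", yt), ("y_pred", yp)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    cm = np.zeros((2, 2), dtype=int)
    for t in (0, 1):
        for p in (0, 1):
            cm[t, p] = int(((yt == t) & (yp == p)).sum())
    return cm


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def classification_report(
    confusion: np.ndarray,
    chance: float | None = None,
    dice: Tuple[float, float, float] | None = None,
) -> EvaluationReport:
    """Per-class and aggregate metrics from a 2×2 confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion must be a 2x2 non-negative count matrix")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    flagged = False
    per_class = {}
    for c in (0, 1):
        precision, f1_p = _safe_div(cm[c, c], cm[:, c].sum())
        recall, f1_r = _safe_div(cm[c, c], cm[c, :].sum())
        f1, f1_h = _safe_div(2 * precision * recall, precision + recall)
        flagged |= f1_p or f1_r or f1_h
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": int(cm[c, :].sum()),
        }
    if flagged:
        warnings.warn("zero denominator in a per-class metric; reported as 0")
    accuracy = float(np.trace(cm) / total)
    supports = np.array([per_class[c]["support"] for c in (0, 1)], dtype=float)
    stack = np.array(
        [[per_class[c][k] for k in ("precision", "recall", "f1")] for c in (0, 1)]
    )
    macro = tuple(stack.mean(axis=0))
    weighted = tuple((stack * supports[:, None]).sum(axis=0) / supports.sum())
    return EvaluationReport(
        confusion=np.asarray(confusion, dtype=int),
        per_class=per_class,
        accuracy=accuracy,
        macro=macro,
        weighted=weighted,
        chance=chance,
        dice_per_class=dice,
        zero_division_flag=bool(flagged),
    )


def chance_baseline(labels: Sequence[int]) -> float:
    """Accuracy of always predicting the most frequent class."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("empty label sequence")
    _, counts = np.unique(lab, return_counts=True)
    return float(counts.max() / lab.size)


def dice_per_class(
    pred_mask: TernaryMask | np.ndarray, true_mask: TernaryMask | np.ndarray
) -> Tuple[float, float, float]:
    """Plain per-class dice 2|P∩T| / (|P| + |T|); both-empty → 1."""
    p = pred_mask.labels if isinstance(pred_mask, TernaryMask) else np.asarray(pred_mask)
    t = true_mask.labels if isinstance(true_mask, TernaryMask) else np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    out = []
    for c in range(3):
        pc = p == c
        tc = t == c
        denom = pc.sum() + tc.sum()
        if denom == 0:
            out.append(1.0)
        else:
            out.append(float(2 * (pc & tc).sum() / denom))
    return tuple(out)


def average_dice(pred_masks, true_masks) -> Tuple[float, float, float]:
    """Dataset-level dice: the per-sample mean of each class's dice."""
    scores = np.array([dice_per_class(p, t) for p, t in zip(pred_masks, true_masks)])
    if scores.size == 0:
        raise ValueError("no mask pairs given")
    return tuple(scores.mean(axis=0))
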