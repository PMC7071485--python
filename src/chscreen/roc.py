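"""ROC curves, AUC with Hanley-McNeil inference, and cut-off selection.

Positivity is strict: a patient tests positive when score > threshold, so a
reported cut-off of 25 means "score above 25 screens positive".  Thresholds
are the distinct observed scores; two virtual endpoints (+inf -> (0,0),
-inf -> (1,1)) close the curve.  The optimal cut-off is the operating point
closest (Euclidean) to the top-left corner (FPR 0, TPR 1); ties break toward
the lower threshold, i.e. toward higher sensitivity, which suits a screening
instrument.  Alongside the observed-score cut-off, the midpoint between the
cut-off and the next higher observed score is reported, since half-integer
cut-offs in the literature arise that way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import Diagnosis

__all__ = ["RocPoint", "RocCurve", "RocResult", "roc_curve", "auc", "best_cutoff"]


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    fpr: float
    tpr: float


@dataclass(frozen=True)
class RocCurve:
    """Operating points ordered by decreasing threshold (increasing FPR/TPR)."""

    points: tuple[RocPoint, ...]
    n_pos: int
    n_neg: int

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p.fpr for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p.tpr for p in self.points])

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p.threshold for p in self.points])


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_se: float
    p_value: float
    cutoff: float
    cutoff_midpoint: float
    sens_at_cutoff: float  # percent
    spec_at_cutoff: float  # percent
    curve: RocCurve


def _split_scores(scores: Sequence, labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    lab = pd.Series(list(labels)).map(
        lambda x: x.value if isinstance(x, Diagnosis) else x
    )
    sc = pd.to_numeric(pd.Series(list(scores)), errors="coerce")
    if len(lab) != len(sc):
        raise ValueError("scores and labels must have equal length")
    keep = lab.notna() & sc.notna()
    lab, sc = lab[keep], sc[keep]
    pos = sc[lab == Diagnosis.CH.value].to_numpy(float)
    neg = sc[lab == Diagnosis.MIGRAINE.value].to_numpy(float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one CH and one migraine score")
    return pos, neg


def roc_curve(scores: Sequence, labels: Sequence) -> RocCurve:
    """Build the empirical ROC curve (positive test: score > threshold)."""
    pos, neg = _split_scores(scores, labels)
    pts = [RocPoint(math.inf, 0.0, 0.0)]
    for t in sorted(np.unique(np.concatenate([pos, neg])))[::-1]:
        pts.append(
            RocPoint(
                threshold=float(t),
                fpr=float(np.mean(neg > t)),
                tpr=float(np.mean(pos > t)),
            )
        )
    pts.append(RocPoint(-math.inf, 1.0, 1.0))
    return RocCurve(points=tuple(pts), n_pos=len(pos), n_neg=len(neg))


def _trapezoid_auc(curve: RocCurve) -> float:
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auc(curve: RocCurve) -> RocResult:
    """Trapezoid AUC with Hanley-McNeil SE and a two-sided z-test vs 0.5.

    The trapezoid area equals the tie-corrected rank statistic
    P(score_CH > score_mig) + 0.5 * P(equal).  A degenerate SE (perfect or
    perfectly reversed separation) yields the smallest representable p-value
    rather than 0, keeping p in (0, 1].
    """
    a = _trapezoid_auc(curve)
    se = _hanley_mcneil_se(a, curve.n_pos, curve.n_neg)
    if se > 0:
        z = (a - 0.5) / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = 1.0 if a == 0.5 else 0.0
    p = float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))
    cut, sens, spec, mid = _best_cutoff_full(curve)
    return RocResult(
        auc=a,
        auc_se=se,
        p_value=p,
        cutoff=cut,
        cutoff_midpoint=mid,
        sens_at_cutoff=sens,
        spec_at_cutoff=spec,
        curve=curve,
    )


def _best_cutoff_full(curve: RocCurve) -> tuple[float, float, float, float]:
    best: Optional[RocPoint] = None
    best_d = math.inf
    for p in curve.points:
        d = math.hypot(1.0 - p.tpr, p.fpr)
        # <= prefers later points, i.e. lower thresholds / higher sensitivity
        if d <= best_d:
            best_d = d
            best = p
    assert best is not None
    finite = [t for t in curve.thresholds if math.isfinite(t)]
    higher = [t for t in finite if t > best.threshold]
    mid = (best.threshold + min(higher)) / 2.0 if higher else best.threshold
    return best.threshold, 100.0 * best.tpr, 100.0 * (1.0 - best.fpr), mid


def best_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold minimising distance to (FPR 0, TPR 1): (cutoff, sens%, spec%)."""
    cut, sens, spec, _ = _best_cutoff_full(curve)
    return cut, sens, spec


def plot_curve(curve: RocCurve, ax=None, label: Optional[str] = None):
    """Plot FPR vs TPR; requires matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.fpr, curve.tpr, marker=".", label=label)
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    if label:
        ax.legend()
    return ax
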