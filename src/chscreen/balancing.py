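"""Class-balanced ROC analysis via repeated majority-class under-sampling.

The study cohort has far more migraine than cluster-headache patients.  To
check that this imbalance does not distort the ROC analysis, the majority
class is repeatedly down-sampled (without replacement) to the minority-class
size, a ROC curve is computed per replicate, and the curves are vertically
averaged: each replicate's TPR is linearly interpolated at a fixed FPR grid
and a normal-approximation 95% band (mean +/- 1.96 SD across replicates,
clipped to [0, 1]) is attached.  Ten replicates is the default; with so few,
sampling variability is reported by the band, not suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .instrument import Diagnosis
from . import roc as roc_mod

__all__ = ["AveragedRoc", "balanced_roc"]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AveragedRoc:
    """Vertically averaged ROC over under-sampling replicates."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    replicate_aucs: list[float]
    n_replicates: int
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.replicate_aucs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fpr": self.fpr_grid,
                "mean_tpr": self.mean_tpr,
                "band_lo": self.band_lo,
                "band_hi": self.band_hi,
            }
        )

    def to_dict(self) -> dict:
        return {
            "fpr_grid": self.fpr_grid.tolist(),
            "mean_tpr": self.mean_tpr.tolist(),
            "band_lo": self.band_lo.tolist(),
            "band_hi": self.band_hi.tolist(),
            "replicate_aucs": self.replicate_aucs,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            **self.metadata,
        }


def _interp_tpr(curve: roc_mod.RocCurve, grid: np.ndarray) -> np.ndarray:
    fpr, tpr = curve.fpr, curve.tpr
    out = np.interp(grid, fpr, tpr)
    # conventions at the closed ends of the grid
    out[grid <= 0.0] = 0.0
    out[grid >= 1.0] = 1.0
    return out


def balanced_roc(
    scores: Sequence,
    labels: Sequence,
    n_replicates: int = 10,
    seed: Optional[int] = None,
    grid_size: int = 101,
) -> AveragedRoc:
    """Average ROC curves over random under-samplings of the majority class.

    Each replicate keeps every minority-class patient and draws, without
    replacement, an equal-sized subset of the majority class.  Fixing ``seed``
    fixes the replicate composition bit-for-bit.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (band undefined otherwise)")
    lab = pd.Series(list(labels)).map(
        lambda x: x.value if isinstance(x, Diagnosis) else x
    )
    sc = pd.to_numeric(pd.Series(list(scores)), errors="coerce")
    keep = lab.notna() & sc.notna()
    lab, sc = lab[keep].to_numpy(), sc[keep].to_numpy(float)

    classes, counts = np.unique(lab, return_counts=True)
    if len(classes) != 2:
        raise ValueError("balanced_roc needs exactly two classes present")
    order = np.argsort(counts, kind="stable")
    minority, majority = classes[order[0]], classes[order[1]]
    n_min = int(counts.min())
    if n_min < 2:
        raise ValueError("minority class must have at least 2 members")

    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, grid_size)
    min_idx = np.flatnonzero(lab == minority)
    maj_idx = np.flatnonzero(lab == majority)

    tprs = np.empty((n_replicates, grid_size))
    aucs: list[float] = []
    for r in range(n_replicates):
        sub = rng.choice(maj_idx, size=n_min, replace=False)
        idx = np.concatenate([min_idx, sub])
        curve = roc_mod.roc_curve(sc[idx], lab[idx])
        tprs[r] = _interp_tpr(curve, grid)
        aucs.append(roc_mod.auc(curve).auc)

    mean = tprs.mean(axis=0)
    sd = tprs.std(axis=0, ddof=1)
    lo = np.clip(mean - _Z95 * sd, 0.0, 1.0)
    hi = np.clip(mean + _Z95 * sd, 0.0, 1.0)
    # band must bracket the mean even at clipped endpoints
    lo = np.minimum(lo, mean)
    hi = np.maximum(hi, mean)
    return AveragedRoc(
        fpr_grid=grid,
        mean_tpr=mean,
        band_lo=lo,
        band_hi=hi,
        replicate_aucs=aucs,
        n_replicates=n_replicates,
        seed=seed,
        metadata={"minority_class": str(minority), "n_per_class": n_min},
    )
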