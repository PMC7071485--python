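"""2x2 diagnostic-accuracy statistics for dichotomous screening items.

Cluster headache (CH) is the disease-positive class throughout; migraine is
the control class.  Metrics are reported as percentages with 95% Wald
confidence intervals clipped to [0, 100]; likelihood ratios as plain ratios.

Counts may be fractional: a published per-group frequency table (percentage p
within a group of size n) converts to expected counts p*n without committing
to an integer rounding, and every metric formula is rate-based, so fractional
tables are legitimate inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .instrument import Diagnosis

__all__ = [
    "ConfusionCounts",
    "CIValue",
    "DiagnosticMetrics",
    "confusion_counts",
    "diagnostic_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """A 2x2 table of (possibly fractional) counts; CH positive, migraine negative."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.tp + self.fn <= 0:
            raise ValueError("no disease-positive (CH) mass: tp + fn must be > 0")
        if self.tn + self.fp <= 0:
            raise ValueError("no control (migraine) mass: tn + fp must be > 0")

    @property
    def n_pos(self) -> float:
        return self.tp + self.fn

    @property
    def n_neg(self) -> float:
        return self.tn + self.fp


@dataclass(frozen=True)
class CIValue:
    """A point estimate on the percent scale with its 95% CI."""

    point: float
    lo: float
    hi: float

    def rounded(self) -> tuple[int, int, int]:
        return round(self.point), round(self.lo), round(self.hi)

    def __str__(self) -> str:
        return f"{self.point:.0f} ({self.lo:.0f};{self.hi:.0f})"


@dataclass
class DiagnosticMetrics:
    """Sensitivity/specificity family on the percent scale, with LRs.

    ``ppv``/``npv`` are ``None`` (and a note is appended to ``flags``) when
    their denominator is zero; ``lr_pos`` is ``inf`` when specificity is 100.
    """

    counts: ConfusionCounts
    sensitivity: CIValue
    specificity: CIValue
    ppv: Optional[CIValue]
    npv: Optional[CIValue]
    fpr: CIValue
    fnr: CIValue
    lr_pos: float
    lr_neg: float
    flags: list[str] = field(default_factory=list)


def confusion_counts(
    labels: Sequence, positives: Sequence, item: str = "item"
) -> ConfusionCounts:
    """Cross-tabulate diagnosis labels against test positivity.

    Pairs where either entry is missing are dropped (pairwise deletion).
    ``labels`` holds ``"CH"``/``"migraine"`` (or :class:`Diagnosis`);
    ``positives`` is boolean-like.
    """
    lab = pd.Series(list(labels)).map(lambda x: x.value if isinstance(x, Diagnosis) else x)
    pos = pd.Series(list(positives))
    if len(lab) != len(pos):
        raise ValueError("labels and positives must have equal length")
    keep = lab.notna() & pos.notna()
    lab, pos = lab[keep], pos[keep].astype(bool)
    if lab.empty:
        raise ValueError(f"{item}: no complete (label, result) pairs")
    is_ch = lab == Diagnosis.CH.value
    return ConfusionCounts(
        tp=float((is_ch & pos).sum()),
        fn=float((is_ch & ~pos).sum()),
        fp=float((~is_ch & pos).sum()),
        tn=float((~is_ch & ~pos).sum()),
    )


def _wald_ci(p_pct: float, n: float, alpha: float) -> tuple[float, float]:
    """Wald normal-approximation CI on the percent scale, clipped to [0, 100]."""
    z = stats.norm.ppf(1 - alpha / 2)
    p = p_pct / 100.0
    half = 100.0 * z * math.sqrt(p * (1 - p) / n)
    return max(0.0, p_pct - half), min(100.0, p_pct + half)


def _civ(p_pct: float, n: float, alpha: float) -> CIValue:
    lo, hi = _wald_ci(p_pct, n, alpha)
    return CIValue(point=p_pct, lo=lo, hi=hi)


def diagnostic_metrics(c: ConfusionCounts, alpha: float = 0.05) -> DiagnosticMetrics:
    """Compute the Se/Sp/PPV/NPV/FPR/FNR/LR family from a 2x2 table.

    Complements are exact before rounding: sensitivity + FNR = 100 and
    specificity + FPR = 100.  FPR/FNR intervals are the mirrored Se/Sp
    intervals, so the complement identity holds for the bounds too.
    """
    flags: list[str] = []
    sens = 100.0 * c.tp / c.n_pos
    spec = 100.0 * c.tn / c.n_neg
    sens_ci = _civ(sens, c.n_pos, alpha)
    spec_ci = _civ(spec, c.n_neg, alpha)
    fnr_ci = CIValue(100.0 - sens, 100.0 - sens_ci.hi, 100.0 - sens_ci.lo)
    fpr_ci = CIValue(100.0 - spec, 100.0 - spec_ci.hi, 100.0 - spec_ci.lo)

    n_test_pos = c.tp + c.fp
    n_test_neg = c.tn + c.fn
    if n_test_pos > 0:
        ppv = _civ(100.0 * c.tp / n_test_pos, n_test_pos, alpha)
    else:
        ppv = None
        flags.append("ppv undefined: no test-positive mass")
    if n_test_neg > 0:
        npv = _civ(100.0 * c.tn / n_test_neg, n_test_neg, alpha)
    else:
        npv = None
        flags.append("npv undefined: no test-negative mass")

    lr_pos = math.inf if spec == 100.0 else sens / (100.0 - spec)
    if spec == 100.0:
        flags.append("lr+ infinite: specificity is 100%")
    lr_neg = math.inf if spec == 0.0 else (100.0 - sens) / spec
    if spec == 0.0:
        flags.append("lr- infinite: specificity is 0%")

    return DiagnosticMetrics(
        counts=c,
        sensitivity=sens_ci,
        specificity=spec_ci,
        ppv=ppv,
        npv=npv,
        fpr=fpr_ci,
        fnr=fnr_ci,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        flags=flags,
    )


def metrics_table(named_metrics: dict[str, DiagnosticMetrics]) -> pd.DataFrame:
    """Render a per-item accuracy table with 'point (lo;hi)' cells.

    Rounding to integer percent happens only here; the DiagnosticMetrics
    objects keep full precision.
    """
    rows = []
    for name, m in named_metrics.items():
        rows.append(
            {
                "test_item": name,
                "sensitivity": str(m.sensitivity),
                "specificity": str(m.specificity),
                "ppv": str(m.ppv) if m.ppv is not None else "undefined",
                "npv": str(m.npv) if m.npv is not None else "undefined",
                "fpr": str(m.fpr),
                "fnr": str(m.fnr),
                "lr_pos": "inf" if math.isinf(m.lr_pos) else f"{m.lr_pos:.2f}",
                "lr_neg": "inf" if math.isinf(m.lr_neg) else f"{m.lr_neg:.2f}",
                "tp": m.counts.tp,
                "fp": m.counts.fp,
                "tn": m.counts.tn,
                "fn": m.counts.fn,
                "flags": "; ".join(m.flags),
            }
        )
    return pd.DataFrame(rows)
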