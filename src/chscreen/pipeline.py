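"""End-to-end study orchestration: simulate/load -> score -> evaluate -> report.

Reproduces the published analysis plan on any cohort table: per-diagnosis
frequency distributions, the dichotomous-item accuracy table, ROC cut-off
tables for the ordinal items and both totals, sex-stratified ROC analysis
(with class balancing inside the female stratum, which is heavily
imbalanced), class-balanced ROC for the whole cohort, and per-group mean
total scores with t-based 95% CIs.

Item-level analyses use pairwise deletion (each record counts toward an item
iff that answer is present); total-score analyses use complete cases.
Percentages are rounded to integers only in the rendered tables; the report
object keeps full precision, and every percentage is recomputable from the
counts the report stores.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import balancing, diagnostics, roc
from .instrument import (
    DICHOTOMOUS_TEST_ITEMS,
    Diagnosis,
    ItemId,
    canonical_items,
    score_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "frequency_table",
           "mean_total_scores", "write_report"]

#: Items analysed with ROC curves (ordinal/continuous), plus the two totals.
ROC_ITEMS: tuple[str, ...] = (
    ItemId.NATURE_OF_PAIN.value,
    ItemId.IMAGE_PREFERENCE.value,
    ItemId.INTENSITY.value,
    ItemId.PAIN_SCALE.value,
    "total_score",
    "total_no_images",
)


@dataclass(frozen=True)
class StudyConfig:
    alpha: float = 0.05
    n_balance_replicates: int = 10
    seed: Optional[int] = None
    stratify_by_sex: bool = True
    balance: bool = True


@dataclass
class StudyReport:
    frequency_table: pd.DataFrame
    item_metrics: dict[str, diagnostics.DiagnosticMetrics]
    roc_table: pd.DataFrame
    roc_results: dict[str, roc.RocResult]
    stratified_roc: dict[str, pd.DataFrame]
    balanced_roc: dict[str, balancing.AveragedRoc]
    mean_scores: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def item_metrics_table(self) -> pd.DataFrame:
        return diagnostics.metrics_table(self.item_metrics)


def frequency_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-diagnosis counts and percentages for every item category.

    Percentages are within diagnosis on per-item denominators (missing
    answers excluded item by item).  An item with no observed answers in a
    group is flagged rather than reported as zeros.
    """
    items = {d.item_id: d for d in canonical_items()}
    rows = []
    for iid, item in items.items():
        col = cohort[iid.value]
        for diag in Diagnosis:
            sub = col[cohort["diagnosis"] == diag.value]
            n_answered = int(sub.notna().sum())
            if n_answered == 0:
                rows.append({
                    "item": iid.value, "diagnosis": diag.value, "category": None,
                    "count": 0, "percent": float("nan"), "n_answered": 0,
                    "flag": "no observed answers",
                })
                continue
            counts = sub.value_counts()
            for cat in item.categories:
                c = int(counts.get(cat, 0))
                rows.append({
                    "item": iid.value, "diagnosis": diag.value, "category": cat,
                    "count": c, "percent": 100.0 * c / n_answered,
                    "n_answered": n_answered, "flag": "",
                })
    return pd.DataFrame(rows)


def mean_total_scores(
    scored: pd.DataFrame, alpha: float = 0.05,
    column: str = "total_score",
) -> pd.DataFrame:
    """Per-diagnosis mean total score with a t-based CI on complete cases."""
    rows = []
    for diag in Diagnosis:
        vals = scored.loc[scored["diagnosis"] == diag.value, column].dropna()
        n = len(vals)
        if n < 2:
            rows.append({"diagnosis": diag.value, "n": n, "mean": float("nan"),
                         "ci_lo": float("nan"), "ci_hi": float("nan"),
                         "flag": "fewer than 2 complete cases"})
            continue
        m = float(vals.mean())
        sem = float(vals.std(ddof=1)) / math.sqrt(n)
        if sem > 0:
            lo, hi = stats.t.interval(1 - alpha, df=n - 1, loc=m, scale=sem)
        else:
            lo = hi = m
        rows.append({"diagnosis": diag.value, "n": n, "mean": m,
                     "ci_lo": float(lo), "ci_hi": float(hi), "flag": ""})
    return pd.DataFrame(rows)


def _roc_table(scored: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, roc.RocResult]]:
    rows, results = [], {}
    for name in ROC_ITEMS:
        col = f"score_{name}" if not name.startswith("total") else name
        res = roc.auc(roc.roc_curve(scored[col], scored["diagnosis"]))
        results[name] = res
        rows.append({
            "test_item": name,
            "cutoff": res.cutoff,
            "cutoff_midpoint": res.cutoff_midpoint,
            "sensitivity_pct": res.sens_at_cutoff,
            "specificity_pct": res.spec_at_cutoff,
            "auc": res.auc,
            "auc_se": res.auc_se,
            "p_value": res.p_value,
        })
    return pd.DataFrame(rows), results


def run_study(cohort: pd.DataFrame, config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the full analysis on a cohort table in the instrument CSV schema."""
    present = set(cohort["diagnosis"].dropna().unique())
    if present != {d.value for d in Diagnosis}:
        raise ValueError(f"cohort must contain both diagnosis classes, has {sorted(present)}")

    scored = score_frame(cohort)
    n_complete = int(scored["total_score"].notna().sum())
    logger.info("scored %d records (%d complete cases)", len(scored), n_complete)

    freq = frequency_table(cohort)

    item_metrics: dict[str, diagnostics.DiagnosticMetrics] = {}
    for iid in DICHOTOMOUS_TEST_ITEMS:
        s = scored[f"score_{iid.value}"]
        counts = diagnostics.confusion_counts(
            scored["diagnosis"], s.map({1.0: True, 0.0: False}), item=iid.value
        )
        item_metrics[iid.value] = diagnostics.diagnostic_metrics(counts, config.alpha)

    roc_table, roc_results = _roc_table(scored)

    stratified: dict[str, pd.DataFrame] = {}
    balanced: dict[str, balancing.AveragedRoc] = {}
    if config.stratify_by_sex:
        for sex in ("male", "female"):
            sub = scored[scored["sex"] == sex]
            if sub["diagnosis"].nunique() < 2:
                logger.warning("sex stratum %s lacks both classes; skipped", sex)
                continue
            stratified[sex], _ = _roc_table(sub)
            if config.balance and sex == "female":
                balanced["female"] = balancing.balanced_roc(
                    sub["total_score"], sub["diagnosis"],
                    n_replicates=config.n_balance_replicates, seed=config.seed,
                )
    if config.balance:
        balanced["all"] = balancing.balanced_roc(
            scored["total_score"], scored["diagnosis"],
            n_replicates=config.n_balance_replicates, seed=config.seed,
        )

    means = mean_total_scores(scored, config.alpha)

    flags = [f"{k}: {f}" for k, m in item_metrics.items() for f in m.flags]
    report = StudyReport(
        frequency_table=freq,
        item_metrics=item_metrics,
        roc_table=roc_table,
        roc_results=roc_results,
        stratified_roc=stratified,
        balanced_roc=balanced,
        mean_scores=means,
        metadata={
            "n_records": int(len(scored)),
            "n_complete_cases": n_complete,
            "n_ch": int((scored["diagnosis"] == "CH").sum()),
            "n_migraine": int((scored["diagnosis"] == "migraine").sum()),
            "config": asdict(config),
            "flags": flags,
        },
    )
    return report


def write_report(report: StudyReport, outdir) -> None:
    """Write the report as per-table CSVs plus a JSON bundle."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.frequency_table.to_csv(out / "frequency_table.csv", index=False)
    report.item_metrics_table().to_csv(out / "item_metrics.csv", index=False)
    report.roc_table.to_csv(out / "roc_table.csv", index=False)
    for sex, tbl in report.stratified_roc.items():
        tbl.to_csv(out / f"roc_table_{sex}.csv", index=False)
    for name, avg in report.balanced_roc.items():
        avg.to_frame().to_csv(out / f"balanced_roc_{name}.csv", index=False)
    report.mean_scores.to_csv(out / "mean_total_scores.csv", index=False)
    bundle = {
        "metadata": report.metadata,
        "mean_scores": report.mean_scores.to_dict(orient="records"),
        "roc_table": report.roc_table.to_dict(orient="records"),
        "balanced_roc": {k: v.to_dict() for k, v in report.balanced_roc.items()},
    }
    (out / "report.json").write_text(json.dumps(bundle, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
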