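"""Synthetic cohort generation from published per-diagnosis marginals.

No patient-level data accompany the study, but the per-diagnosis frequency
distribution of every questionnaire item is published, together with the
cohort composition (81 CH patients: 45 chronic / 36 episodic, 51 male /
30 female; 215 migraine patients: 123 chronic / 92 episodic, 35 male /
180 female; ages 18-79).  This module turns those numbers into a generative
model: each patient's 12 answers are drawn independently from their
diagnosis group's categorical marginals, ages uniformly on the printed range.

Items are independent within a patient by construction — the published
tables carry no dependence structure, and none is invented.  Marginal
statistics (per-item frequencies, expected total score) are therefore
faithful, while joint-score statistics (e.g. the published total-score
cut-off's sensitivity) are not guaranteed to be reproduced.  A
``joint_sampler`` hook accepts a user-supplied sampler for sensitivity
analyses with dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Optional

import numpy as np
import yaml

from .instrument import (
    Diagnosis,
    ItemId,
    ItemDefinition,
    ResponseRecord,
    canonical_items,
    cohort_to_frame,
)

__all__ = [
    "MarginalSpec",
    "CohortSpec",
    "default_spec",
    "generate",
    "generate_frame",
    "expected_item_score",
    "expected_total_score",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class MarginalSpec:
    """Per-group, per-item categorical probabilities (plus missingness).

    ``raw_percent`` keeps the values exactly as published (they may sum to
    99.9 or 100.1); ``probs`` renormalises them to proper probability
    vectors.  ``missingness`` is the per-item probability that the answer is
    absent (default 0 everywhere).
    """

    raw_percent: dict[str, dict[ItemId, dict[str, float]]]
    missingness: dict[str, dict[ItemId, float]] = field(default_factory=dict)

    def probs(self, group: str, item: ItemId) -> dict[str, float]:
        raw = self.raw_percent[group][item]
        total = sum(raw.values())
        if total <= 0:
            raise ValueError(f"{group}/{item!s}: non-positive probability mass")
        out = {k: v / total for k, v in raw.items()}
        assert abs(sum(out.values()) - 1.0) < _PROB_TOL
        return out

    def missing_prob(self, group: str, item: ItemId) -> float:
        return self.missingness.get(group, {}).get(item, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes, demographic splits, and marginals driving a simulation."""

    n_ch: int
    n_migraine: int
    subtype_split: dict[str, dict[str, int]]
    sex_split: dict[str, dict[str, int]]
    age_range: tuple[int, int]
    marginals: MarginalSpec
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for group, total in ((Diagnosis.CH.value, self.n_ch),
                             (Diagnosis.MIGRAINE.value, self.n_migraine)):
            for name, split in (("subtype", self.subtype_split),
                                ("sex", self.sex_split)):
                if sum(split[group].values()) != total:
                    raise ValueError(
                        f"{name} split for {group} sums to "
                        f"{sum(split[group].values())}, expected {total}"
                    )

    def with_scale(self, factor: int) -> "CohortSpec":
        """Scale every group and split count by an integer factor."""
        return replace(
            self,
            n_ch=self.n_ch * factor,
            n_migraine=self.n_migraine * factor,
            subtype_split={
                g: {k: v * factor for k, v in d.items()}
                for g, d in self.subtype_split.items()
            },
            sex_split={
                g: {k: v * factor for k, v in d.items()}
                for g, d in self.sex_split.items()
            },
        )


def default_spec() -> CohortSpec:
    """The canonical study spec shipped with the package."""
    text = resources.files("chscreen.data").joinpath("cohort_spec.yaml").read_text()
    raw = yaml.safe_load(text)
    marg = {
        group: {ItemId(item): {str(k): float(v) for k, v in cats.items()}
                for item, cats in items.items()}
        for group, items in raw["marginals_percent"].items()
    }
    return CohortSpec(
        n_ch=int(raw["n_ch"]),
        n_migraine=int(raw["n_migraine"]),
        subtype_split=raw["subtype_split"],
        sex_split=raw["sex_split"],
        age_range=tuple(raw["age_range"]),
        marginals=MarginalSpec(raw_percent=marg),
    )


def _group_assignments(
    split: dict[str, int], rng: np.random.Generator
) -> np.ndarray:
    vals = np.concatenate([[k] * n for k, n in split.items()])
    return rng.permutation(vals)


def generate(
    spec: CohortSpec,
    seed: Optional[int] = None,
    joint_sampler: Optional[
        Callable[[str, int, np.random.Generator], list[dict[ItemId, Optional[str]]]]
    ] = None,
) -> list[ResponseRecord]:
    """Draw a cohort with exactly the specified counts; deterministic per seed.

    ``joint_sampler(group, n, rng)`` may replace the independent per-item
    draws with answer dictionaries from a dependent joint model.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    lo, hi = spec.age_range
    records: list[ResponseRecord] = []
    for diag, n in ((Diagnosis.CH, spec.n_ch), (Diagnosis.MIGRAINE, spec.n_migraine)):
        group = diag.value
        subtypes = _group_assignments(spec.subtype_split[group], rng)
        sexes = _group_assignments(spec.sex_split[group], rng)
        ages = rng.integers(lo, hi + 1, size=n)
        if joint_sampler is not None:
            answer_sets = joint_sampler(group, n, rng)
            if len(answer_sets) != n:
                raise ValueError("joint_sampler returned the wrong cohort size")
        else:
            answer_sets = _independent_answers(spec, group, n, rng)
        for i in range(n):
            records.append(
                ResponseRecord(
                    patient_id=f"{group}-{i:04d}",
                    diagnosis=diag,
                    subtype=str(subtypes[i]),
                    sex=str(sexes[i]),
                    age=int(ages[i]),
                    answers=answer_sets[i],
                )
            )
    return records


def _independent_answers(
    spec: CohortSpec, group: str, n: int, rng: np.random.Generator
) -> list[dict[ItemId, Optional[str]]]:
    answers: list[dict[ItemId, Optional[str]]] = [{} for _ in range(n)]
    for item in ItemId:
        p = spec.marginals.probs(group, item)
        cats = list(p.keys())
        draws = rng.choice(len(cats), size=n, p=list(p.values()))
        miss_p = spec.marginals.missing_prob(group, item)
        missing = (
            rng.random(n) < miss_p if miss_p > 0 else np.zeros(n, dtype=bool)
        )
        for i in range(n):
            answers[i][item] = None if missing[i] else cats[draws[i]]
    return answers


def generate_frame(spec: CohortSpec, seed: Optional[int] = None, **kw):
    """Generate a cohort directly in the cohort CSV schema."""
    return cohort_to_frame(generate(spec, seed=seed, **kw))


def expected_item_score(
    spec: CohortSpec, group: str, item: ItemId,
    items: Optional[tuple[ItemDefinition, ...]] = None,
) -> float:
    """E[coded score] of one item under a group's (renormalised) marginal."""
    defs = {d.item_id: d for d in (items or canonical_items())}
    code = defs[item].code_map
    return sum(p * code[cat] for cat, p in spec.marginals.probs(group, item).items())


def expected_total_score(
    spec: CohortSpec, group: str, include_images: bool = True
) -> float:
    """E[total score] by linearity of expectation over the 12 items."""
    items = [
        i for i in ItemId
        if include_images or i is not ItemId.IMAGE_PREFERENCE
    ]
    defs = canonical_items()
    return sum(expected_item_score(spec, group, i, defs) for i in items)
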